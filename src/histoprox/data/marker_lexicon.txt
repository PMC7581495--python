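ihc
immunohistochemistry
immunostain
fish
desmin
ki-67
ki67
her2
s100
vimentin
cytokeratin
p53
p16
p63
cdx2
ttf-1
ttf1
pax8
gata3
synaptophysin
chromogranin
re:cd\d+
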
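h&e	HE	0
he	HE	1
hematoxylin	HE	1
eosin	HE	1
ihc	IHC	0
immunohistochemistry	IHC	0
immunostain	IHC	1
chromogen	IHC	1
giemsa	other	1
trichrome	other	1
pas	other	1
gram	other	1
silver	other	1
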
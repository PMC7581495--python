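"""Weak-supervision labeling from case text.

Social-media pathology posts carry their ground truth in hashtags (e.g.
``#dermpath``, ``#cancer``) and free-text keywords ("ovarian" indicates
gynecological pathology, "carcinoma in situ" indicates low-grade disease).
This module maps post text, replies and hashtags onto the canonical tissue,
disease-state and stain vocabularies via editable plain-text rule tables,
detects marker-test mentions (IHC, FISH, specific antibodies), and encodes
the clinical covariates for downstream models.

Missing tissue is encoded as all-zeros for neural consumers and as missing
values for the Random Forest.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

MISSING = "MISSING"

TISSUES = (
    "bone_soft_tissue",
    "breast",
    "dermatological",
    "gastrointestinal",
    "genitourinary",
    "gynecological",
    "head_neck",
    "hematological",
    "neurological",
    "pulmonary",
)
DISEASES = ("nontumor", "low_grade", "malignant")
STAINS = ("HE", "IHC", "other")

_VOCAB = {"tissue": TISSUES, "disease": DISEASES, "stain": STAINS}


class RuleConfigError(ValueError):
    """Malformed rule table or lexicon."""


@dataclass(frozen=True)
class CaseText:
    post_text: str = ""
    reply_texts: tuple = ()
    hashtags: tuple = ()

    def __post_init__(self) -> None:
        norm = tuple(h.lstrip("#").lower() for h in self.hashtags)
        object.__setattr__(self, "hashtags", norm)
        object.__setattr__(self, "reply_texts", tuple(self.reply_texts))


@dataclass
class CaseLabels:
    tissue: str = MISSING
    disease: str = MISSING
    stain: str = MISSING
    marker_mention: bool = False
    acceptable: bool = True

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES + (MISSING,):
            raise ValueError(f"unknown tissue {self.tissue!r}; canonical: {TISSUES}")
        if self.disease not in DISEASES + (MISSING,):
            raise ValueError(f"unknown disease {self.disease!r}; canonical: {DISEASES}")
        if self.stain not in STAINS + (MISSING,):
            raise ValueError(f"unknown stain {self.stain!r}; canonical: {STAINS}")


@dataclass(frozen=True)
class CovariateVector:
    """10-dim tissue one-hot (all zeros + flag when missing) and marker bit."""

    tissue_onehot: np.ndarray
    tissue_missing: bool
    marker: int

    def for_network(self) -> np.ndarray:
        """11-dim input for the neural encoder (zeros when tissue missing)."""
        return np.concatenate([self.tissue_onehot, [self.marker]]).astype(np.float64)

    def for_forest(self) -> np.ndarray:
        """11-dim block for the forest: NaN tissue entries when missing."""
        tissue = (
            np.full(len(TISSUES), np.nan)
            if self.tissue_missing
            else self.tissue_onehot.astype(np.float64)
        )
        return np.concatenate([tissue, [float(self.marker)]])


@dataclass(frozen=True)
class Rule:
    pattern: str
    target: str
    priority: int


class RuleTable:
    """Priority-ordered keyword/hashtag rules for one label field.

    Plain-text format, one rule per line: ``pattern TAB target TAB priority``
    (lower priority number wins; multi-word patterns conventionally get
    priority 0 so "carcinoma in situ" outranks "carcinoma").
    """

    def __init__(self, field_name: str, rules) -> None:
        if field_name not in _VOCAB:
            raise RuleConfigError(f"unknown label field {field_name!r}")
        self.field_name = field_name
        self.rules = tuple(rules)
        vocab = _VOCAB[field_name]
        for r in self.rules:
            if r.target not in vocab:
                raise RuleConfigError(
                    f"rule target {r.target!r} not in {field_name} vocabulary {vocab}"
                )
        self._compiled = [
            (re.compile(r"(?<!\w)" + re.escape(r.pattern) + r"(?!\w)", re.IGNORECASE), r)
            for r in self.rules
        ]

    @classmethod
    def from_text(cls, field_name: str, text: str) -> "RuleTable":
        rules = []
        for ln, line in enumerate(text.splitlines(), start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise RuleConfigError(f"line {ln}: expected 'pattern<TAB>target<TAB>priority'")
            try:
                prio = int(parts[2])
            except ValueError as e:
                raise RuleConfigError(f"line {ln}: priority must be an integer") from e
            rules.append(Rule(parts[0].strip().lower(), parts[1].strip(), prio))
        return cls(field_name, rules)

    @classmethod
    def from_file(cls, field_name: str, path) -> "RuleTable":
        return cls.from_text(field_name, Path(path).read_text())

    @classmethod
    def default(cls, field_name: str) -> "RuleTable":
        fname = {"tissue": "tissue_rules.tsv", "disease": "disease_rules.tsv", "stain": "stain_rules.tsv"}[field_name]
        text = resources.files("histoprox.data").joinpath(fname).read_text()
        return cls.from_text(field_name, text)

    def to_text(self) -> str:
        return "\n".join(f"{r.pattern}\t{r.target}\t{r.priority}" for r in self.rules) + "\n"

    def _unit_matches(self, unit: str, is_hashtag: bool):
        """Fired rules for one text unit, keeping only the best priority."""
        fired = []
        for rx, rule in self._compiled:
            if is_hashtag:
                if unit == rule.pattern.replace(" ", "").replace("&", ""):
                    fired.append(rule)
            elif rx.search(unit):
                fired.append(rule)
        if not fired:
            return []
        best = min(r.priority for r in fired)
        return [r for r in fired if r.priority == best]

    def apply(self, text: CaseText) -> str:
        """Resolve a label: hashtags first, then majority vote across post +
        replies, remaining ties broken by rule priority; MISSING otherwise."""
        units = [(h, True) for h in text.hashtags]
        units.append((text.post_text.lower(), False))
        units.extend((t.lower(), False) for t in text.reply_texts)

        votes: Counter = Counter()
        best_prio: dict = {}
        first_seen: dict = {}
        order = 0
        for unit, is_tag in units:
            for rule in self._unit_matches(unit, is_tag):
                votes[rule.target] += 1
                # hashtag provenance outranks free text at equal priority
                eff = (0 if is_tag else 1, rule.priority)
                if rule.target not in best_prio or eff < best_prio[rule.target]:
                    best_prio[rule.target] = eff
                if rule.target not in first_seen:
                    first_seen[rule.target] = order
                    order += 1
        if not votes:
            return MISSING
        top = max(votes.values())
        leaders = [t for t, v in votes.items() if v == top]
        if len(leaders) == 1:
            return leaders[0]
        leaders.sort(key=lambda t: (best_prio[t], first_seen[t]))
        return leaders[0]


def parse_tissue(text: CaseText, rules: RuleTable | None = None) -> str:
    rules = rules or RuleTable.default("tissue")
    if rules.field_name != "tissue":
        raise RuleConfigError("rule table is not a tissue table")
    return rules.apply(text)


def parse_disease(text: CaseText, rules: RuleTable | None = None) -> str:
    rules = rules or RuleTable.default("disease")
    if rules.field_name != "disease":
        raise RuleConfigError("rule table is not a disease table")
    return rules.apply(text)


def parse_stain(text: CaseText, rules: RuleTable | None = None) -> str:
    rules = rules or RuleTable.default("stain")
    if rules.field_name != "stain":
        raise RuleConfigError("rule table is not a stain table")
    return rules.apply(text)


class MarkerLexicon:
    """Marker-test terms; plain lines are literal words, ``re:`` lines are
    regular expressions (the default includes ``re:cd\\d+`` for CD markers)."""

    def __init__(self, patterns) -> None:
        self.patterns = tuple(patterns)
        self._compiled = [
            re.compile(r"(?<!\w)" + p + r"(?!\w)", re.IGNORECASE)
            for p in self.patterns
        ]

    @classmethod
    def from_text(cls, text: str) -> "MarkerLexicon":
        pats = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pats.append(line[3:] if line.startswith("re:") else re.escape(line))
        return cls(pats)

    @classmethod
    def default(cls) -> "MarkerLexicon":
        return cls.from_text(
            resources.files("histoprox.data").joinpath("marker_lexicon.txt").read_text()
        )


def detect_marker(text: CaseText, lexicon: MarkerLexicon | None = None) -> bool:
    """True iff any marker term appears (word boundary, case-insensitive)
    in the post or any reply."""
    lexicon = lexicon or MarkerLexicon.default()
    for unit in (text.post_text, *text.reply_texts):
        if any(rx.search(unit) for rx in lexicon._compiled):
            return True
    return False


def parse_labels(
    text: CaseText,
    tissue_rules: RuleTable | None = None,
    disease_rules: RuleTable | None = None,
    stain_rules: RuleTable | None = None,
    lexicon: MarkerLexicon | None = None,
) -> CaseLabels:
    return CaseLabels(
        tissue=parse_tissue(text, tissue_rules),
        disease=parse_disease(text, disease_rules),
        stain=parse_stain(text, stain_rules),
        marker_mention=detect_marker(text, lexicon),
    )


def encode_covariates(labels: CaseLabels) -> CovariateVector:
    """One-hot over the canonical 10-tissue order plus the marker bit.

    MISSING tissue -> all-zero one-hot with the missing flag set; the neural
    encoder consumes the zeros, the forest consumes NaNs.
    """
    onehot = np.zeros(len(TISSUES))
    missing = labels.tissue == MISSING
    if not missing:
        if labels.tissue not in TISSUES:
            raise ValueError(
                f"unknown tissue {labels.tissue!r}; canonical vocabulary: {TISSUES}"
            )
        onehot[TISSUES.index(labels.tissue)] = 1.0
    return CovariateVector(
        tissue_onehot=onehot,
        tissue_missing=missing,
        marker=int(labels.marker_mention),
    )
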
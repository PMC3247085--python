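"""Synthetic data generators.

Two generators stand in for the external interaction corpora so every
pipeline stage is testable without downloads:

* ``make_clusters`` draws Gaussian clusters in feature space — the
  geometry the cluster assumption of semi-supervised learning relies on —
  with a labeled/unlabeled/test split and optional label-flip noise.
* ``make_sentences`` fills short English templates with sampled protein
  names and interaction trigger terms.  Positive sentences place a
  trigger between two protein mentions; negative sentences either lack a
  trigger or negate it with a pre-negation phrase.  Gold labels and gold
  mention spans are recorded on every sentence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import Lexicons, Sentence, default_lexicons, tokenize


# ---------------------------------------------------------------------------
# cluster-structured numeric data


@dataclass
class ClusterSpec:
    """Gaussian mixture specification with a labeled/unlabeled/test split."""

    centers: list = field(default_factory=lambda: [(-2.0, 0.0), (2.0, 0.0)])
    sigmas: list = field(default_factory=lambda: [0.5, 0.5])
    class_of_cluster: list = field(default_factory=lambda: [-1, 1])
    n_labeled: int = 2
    n_unlabeled: int = 100
    n_test: int = 100
    label_flip_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        classes = set(self.class_of_cluster)
        if not {-1, 1} <= classes:
            raise ValueError("need at least one cluster per class")
        if not 0 <= self.label_flip_noise < 0.5:
            raise ValueError("label_flip_noise must be in [0, 0.5)")
        if min(self.n_labeled, self.n_unlabeled, self.n_test) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class SplitData:
    X: np.ndarray
    y: np.ndarray


def _draw(spec: ClusterSpec, n: int, rng: np.random.Generator, stratified: bool):
    centers = np.asarray(spec.centers, dtype=float)
    sigmas = np.asarray(spec.sigmas, dtype=float)
    classes = np.asarray(spec.class_of_cluster, dtype=int)
    k, d = centers.shape
    if stratified:
        # at least one point from a cluster of each class
        pos_clusters = np.flatnonzero(classes > 0)
        neg_clusters = np.flatnonzero(classes < 0)
        if n < 2:
            raise ValueError("stratified draw needs n >= 2 (one per class)")
        forced = [rng.choice(pos_clusters), rng.choice(neg_clusters)]
        rest = rng.integers(0, k, size=n - 2)
        which = np.concatenate([forced, rest])
        rng.shuffle(which)
    else:
        which = rng.integers(0, k, size=n)
    X = centers[which] + rng.normal(size=(n, d)) * sigmas[which][:, None]
    y = classes[which].copy()
    if spec.label_flip_noise > 0:
        flip = rng.random(n) < spec.label_flip_noise
        y[flip] = -y[flip]
    return SplitData(X=X, y=y)


def make_clusters(spec: ClusterSpec) -> tuple[SplitData, SplitData, SplitData]:
    """Deterministic per seed: (labeled, unlabeled, test) Gaussian draws.

    The labeled split is stratified so both classes are represented; gold
    labels are retained on the unlabeled split for oracle simulation and
    transductive evaluation.
    """
    rng = np.random.default_rng(spec.seed)
    labeled = _draw(spec, spec.n_labeled, rng, stratified=True) if spec.n_labeled else SplitData(
        np.empty((0, len(spec.centers[0]))), np.empty(0, dtype=int))
    unlabeled = _draw(spec, spec.n_unlabeled, rng, stratified=False)
    test = _draw(spec, spec.n_test, rng, stratified=False)
    return labeled, unlabeled, test


# ---------------------------------------------------------------------------
# templated sentence corpora

#: (template, label, kind); {INT} is filled with the third-person form of a
#: verbal trigger, {NEGPRE} with a pre-negation phrase.
DEFAULT_TEMPLATES: list[tuple[str, int, str]] = [
    ("{P1} {INT} {P2} in vitro .", 1, "positive"),
    ("We show that {P1} directly {INT} {P2} .", 1, "positive"),
    ("The {P1} protein {INT} the {P2} receptor in these cells .", 1, "positive"),
    ("Our results indicate that {P1} specifically {INT} {P2} during stress .", 1, "positive"),
    ("{P1} and {P2} were purified from cell extracts .", -1, "negative"),
    ("{P1} was expressed at high levels ; {P2} localized to the nucleus .", -1, "negative"),
    ("Expression of {P1} increased after treatment with the drug .", -1, "negative"),
    ("{NEGPRE} evidence that {P1} {INT} {P2} was found in our assays .", -1, "negated"),
    ("{NEGPRE} interaction between {P1} and {P2} was detected .", -1, "negated"),
]


@dataclass
class SentenceSpec:
    """Templated corpus specification."""

    n_sentences: int = 500
    templates: list[tuple[str, int, str]] = field(
        default_factory=lambda: list(DEFAULT_TEMPLATES))
    n_proteins: int = 50
    positive_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        kinds = {k for _, _, k in self.templates}
        if "negated" not in kinds:
            raise ValueError("templates must cover at least one negated pattern")


def make_synthetic_lexicons(spec: SentenceSpec) -> Lexicons:
    """Lexicons whose gazetteer holds ``n_proteins`` generated single-token
    protein names on top of the packaged interactor and negation lists."""
    rng = np.random.default_rng(spec.seed)
    base = default_lexicons()
    names = set()
    while len(names) < spec.n_proteins:
        stemmed = "".join(rng.choice(list("bcdfghklmnprstvwz")) for _ in range(3))
        names.add(f"{stemmed.capitalize()}{rng.integers(1, 99)}p")
    gaz = set(base.protein_gazetteer) | {n.lower() for n in names}
    return Lexicons(
        protein_gazetteer=gaz,
        interactor_terms=dict(base.interactor_terms),
        negation_pre=list(base.negation_pre),
        negation_post=list(base.negation_post),
        negation_pseudo=list(base.negation_pseudo),
    )


_VERBAL_TRIGGERS = ("bind", "activate", "inhibit", "phosphorylate", "regulate",
                    "suppress", "stimulate", "recruit", "stabilize")


def _third_person(verb: str) -> str:
    if verb.endswith(("ss", "x", "zz", "ch", "sh")):
        return verb + "es"
    return verb + "s"


def make_sentences(spec: SentenceSpec, lexicons: Lexicons) -> list[Sentence]:
    """Generate a templated corpus with gold labels and gold mention spans.

    Sentences are sampled per class with probability ``positive_fraction``
    for the positive class; slot fills come from the gazetteer (two
    distinct names per sentence) and from the verbal triggers of the
    interactor lexicon (third-person surface forms).
    """
    rng = np.random.default_rng(spec.seed)
    # slot fills must be single tokens so gold spans are one token wide
    proteins = [p for p in sorted(lexicons.protein_gazetteer)
                if len(tokenize(p)) == 1]
    triggers = [t for t in _VERBAL_TRIGGERS if t in lexicons.interactor_terms]
    pos_templates = [t for t in spec.templates if t[1] == 1]
    neg_templates = [t for t in spec.templates if t[1] == -1]
    pre_phrases = [p for p in lexicons.negation_pre if p == "no"] or ["no"]

    sentences = []
    for i in range(spec.n_sentences):
        positive = rng.random() < spec.positive_fraction
        pool = pos_templates if positive else neg_templates
        template, label, _ = pool[rng.integers(0, len(pool))]
        p1, p2 = rng.choice(len(proteins), size=2, replace=False)
        fills = {
            "P1": proteins[p1].capitalize(),
            "P2": proteins[p2].capitalize(),
            "INT": _third_person(triggers[rng.integers(0, len(triggers))]),
            "NEGPRE": pre_phrases[rng.integers(0, len(pre_phrases))].capitalize(),
        }
        try:
            text = template.format(**fills)
        except (KeyError, IndexError) as exc:
            raise ValueError(f"template slot mismatch in {template!r}") from exc
        toks = tokenize(text)
        lower = [t.lower() for t in toks]
        spans = []
        for name in (fills["P1"].lower(), fills["P2"].lower()):
            if name in lower:
                j = lower.index(name)
                spans.append((j, j + 1))
        spans = sorted(set(spans))
        sentences.append(Sentence(id=f"s{i:05d}", text=text,
                                  protein_mentions=spans, label=label))
    return sentences
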
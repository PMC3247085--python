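"""Sentence representation for protein-interaction classification.

A sentence is mapped to nine features: whether it is negated (NegEx-style
pre/post/pseudo phrase matching around "findings"), the number of protein
name occurrences (gazetteer longest-match), the interaction trigger term
("interactor") with its part-of-speech tag and character position, three
positional counts relating the outermost protein mentions to the rest of
the sentence, and whether a grammatical link path plausibly connects the
two outermost proteins.

Undefined positional quantities (fewer than two proteins, a protein at the
sentence start, ...) carry the sentinel value -1; undefined categorical
features carry ``None`` (MISSING).
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MISSING = None

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)

#: Closed POS tag set for the interactor POS feature; anything else maps
#: to OTHER at encoding time.
POS_TAGS = ("VB", "VBD", "VBG", "VBN", "VBP", "VBZ", "NN", "NNS", "JJ", "OTHER")

FEATURE_NAMES = (
    "is_negated",
    "n_protein_occurrences",
    "interactor_name",
    "interactor_pos",
    "interactor_position",
    "n_words_between",
    "n_left_words",
    "n_right_words",
    "link_path",
)


class EmptyTextError(ValueError):
    """Raised when a sentence has no text to tokenize."""


# ---------------------------------------------------------------------------
# tokenization


def tokenize(text: str, with_offsets: bool = False):
    """Split ``text`` into word and punctuation tokens.

    Words are maximal runs of word characters; every other non-space
    character is its own token, so ``"p53-mediated"`` becomes
    ``["p53", "-", "mediated"]``.  With ``with_offsets=True`` the character
    offset of each token in ``text`` is returned alongside, making the
    token -> character mapping recoverable.
    """
    if not text or not text.strip():
        raise EmptyTextError("cannot tokenize empty text")
    tokens, offsets = [], []
    for m in _TOKEN_RE.finditer(text):
        tokens.append(m.group(0))
        offsets.append(m.start())
    if with_offsets:
        return tokens, offsets
    return tokens


@dataclass
class Sentence:
    """One corpus unit: raw text, its tokens, protein mention spans, label.

    ``protein_mentions`` holds half-open ``(start, end)`` token spans; the
    label is +1 (interaction asserted), -1 (no interaction) or ``None``
    (unlabeled).
    """

    id: str
    text: str
    tokens: list[str] = field(default_factory=list)
    token_offsets: list[int] = field(default_factory=list)
    protein_mentions: list[tuple[int, int]] = field(default_factory=list)
    label: int | None = None

    def __post_init__(self):
        if not self.tokens:
            self.tokens, self.token_offsets = tokenize(self.text, with_offsets=True)
        elif not self.token_offsets:
            # best-effort recovery of offsets by sequential search
            pos = 0
            for tok in self.tokens:
                idx = self.text.find(tok, pos)
                self.token_offsets.append(idx if idx >= 0 else pos)
                pos = (idx if idx >= 0 else pos) + len(tok)

    @property
    def lower_tokens(self) -> list[str]:
        return [t.lower() for t in self.tokens]


# ---------------------------------------------------------------------------
# lexicons


@dataclass
class Lexicons:
    """Plain-text lexicons: protein gazetteer, interactor terms with POS,
    and the three NegEx negation phrase lists."""

    protein_gazetteer: set[str]
    interactor_terms: dict[str, str]
    negation_pre: list[str]
    negation_post: list[str]
    negation_pseudo: list[str]

    def __post_init__(self):
        self.protein_gazetteer = {p.lower().strip() for p in self.protein_gazetteer if p.strip()}
        self.interactor_terms = {
            k.lower().strip(): v.strip() for k, v in self.interactor_terms.items() if k.strip()
        }
        self.negation_pre = _dedup_lower(self.negation_pre)
        self.negation_post = _dedup_lower(self.negation_post)
        self.negation_pseudo = _dedup_lower(self.negation_pseudo)
        for name in ("protein_gazetteer", "interactor_terms", "negation_pre",
                     "negation_post", "negation_pseudo"):
            if not getattr(self, name):
                raise ValueError(f"lexicon {name!r} is empty")
        # token forms cached for span matching, grouped by token length
        gaz_tokens = {tuple(tokenize(p)) for p in self.protein_gazetteer}
        self._gaz_by_len: dict[int, set[tuple[str, ...]]] = {}
        for t in gaz_tokens:
            self._gaz_by_len.setdefault(len(t), set()).add(t)
        self._max_gaz_len = max(self._gaz_by_len)


def _dedup_lower(items: Iterable[str]) -> list[str]:
    seen, out = set(), []
    for it in items:
        it = it.lower().strip()
        if it and it not in seen:
            seen.add(it)
            out.append(it)
    return out


def load_lexicons(
    proteins: str | Path,
    interactors: str | Path,
    negation_pre: str | Path,
    negation_post: str | Path,
    negation_pseudo: str | Path,
) -> Lexicons:
    """Load lexicons from one-term-per-line files (interactors: term<TAB>POS)."""

    def lines(p):
        return [ln.strip() for ln in Path(p).read_text(encoding="utf-8").splitlines() if ln.strip()]

    inter = {}
    for ln in lines(interactors):
        term, _, pos = ln.partition("\t")
        inter[term] = pos or "OTHER"
    return Lexicons(
        protein_gazetteer=set(lines(proteins)),
        interactor_terms=inter,
        negation_pre=lines(negation_pre),
        negation_post=lines(negation_post),
        negation_pseudo=lines(negation_pseudo),
    )


def default_lexicons() -> Lexicons:
    """The lexicons shipped with the package (small demonstration gazetteer,
    interaction trigger terms with POS, NegEx phrase lists)."""
    root = resources.files("ppispotter") / "data"
    return load_lexicons(
        root / "proteins.txt",
        root / "interactors.tsv",
        root / "negation_pre.txt",
        root / "negation_post.txt",
        root / "negation_pseudo.txt",
    )


# ---------------------------------------------------------------------------
# stemming

_VOWELS = set("aeiou")


def _undouble(stem: str) -> str | None:
    """Drop a doubled final consonant; None when nothing to undouble."""
    if len(stem) >= 4 and stem[-1] == stem[-2] and stem[-1] not in "lsz" and stem[-1] not in _VOWELS:
        return stem[:-1]
    return None


def _strip_verbal(stem_: str) -> str:
    # a doubled consonant marks a short vowel: undouble and stop; otherwise
    # consider restoring a dropped magic e
    undoubled = _undouble(stem_)
    return undoubled if undoubled is not None else _maybe_restore_e(stem_)


def _maybe_restore_e(stem: str) -> str:
    # CVC ending with a single final consonant usually lost a magic e
    if (
        len(stem) >= 3
        and stem[-1] not in _VOWELS
        and stem[-1] not in "wxy"
        and stem[-2] in _VOWELS
        and stem[-3] not in _VOWELS
    ):
        return stem + "e"
    return stem


def stem(word: str) -> str:
    """Conservative suffix stripper used for interactor lookup.

    Handles plural -s/-es/-ies and verbal -ed/-ing with consonant
    undoubling and magic-e restoration; never shortens a word below three
    characters and deliberately avoids Porter-style aggressiveness so the
    POS of the stemmed term is preserved.
    """
    w = word.lower()
    if len(w) <= 3:
        return w
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("ing") and len(w) - 3 >= 3:
        return _strip_verbal(w[:-3])
    if w.endswith("ed") and len(w) - 2 >= 3:
        return _strip_verbal(w[:-2])
    if w.endswith("es") and any(w.endswith(s + "es") for s in ("ss", "x", "zz", "ch", "sh")):
        return w[:-2]
    if w.endswith("s") and not w.endswith(("ss", "us", "is")) and len(w) - 1 >= 3:
        return w[:-1]
    return w


# ---------------------------------------------------------------------------
# negation (NegEx-style)


def _phrase_matches(lower_tokens: Sequence[str], phrases: Iterable[str]) -> list[tuple[int, int]]:
    """Token spans (half-open) where any phrase occurs; phrases are matched
    on their own tokenization."""
    spans = []
    for phrase in phrases:
        ptoks = tuple(tokenize(phrase))
        n = len(ptoks)
        for i in range(len(lower_tokens) - n + 1):
            if tuple(lower_tokens[i : i + n]) == ptoks:
                spans.append((i, i + n))
    return spans


def _findings(sentence: Sentence, lexicons: Lexicons) -> list[tuple[int, int, str]]:
    """Findings = protein mentions plus interactor-term tokens."""
    if not sentence.protein_mentions:
        count_proteins(sentence, lexicons)
    found = [(s, e, " ".join(sentence.tokens[s:e])) for s, e in sentence.protein_mentions]
    covered = {i for s, e in sentence.protein_mentions for i in range(s, e)}
    for i, tok in enumerate(sentence.lower_tokens):
        if i not in covered and stem(tok) in lexicons.interactor_terms:
            found.append((i, i + 1, sentence.tokens[i]))
    return sorted(found)


_COORDINATION = {",", "and", "or"}
_BOUNDARY = {".", ";", ":", "but"}


def _scope_tokens(toks: Sequence[str], start: int, window: int, step: int) -> set[int]:
    """Token indices inside the negation scope opened at ``start``.

    The scope extends ``window`` tokens in the scan direction, with the
    counter resetting at coordinating tokens (',', 'and', 'or') so that
    negation distributes over coordinated lists; it ends at boundary
    punctuation/conjunctions or as soon as the counter exceeds the window.
    """
    scope = set()
    count = 0
    i = start
    while 0 <= i < len(toks):
        tok = toks[i]
        if tok in _BOUNDARY:
            break
        if tok in _COORDINATION:
            count = 0
        else:
            count += 1
            # a finding at position i has count-1 intervening tokens, so
            # membership at count <= window+1 means a gap of 0..window
            if count > window + 1:
                break
            scope.add(i)
        i += step
    return scope


def detect_negation(
    sentence: Sentence, lexicons: Lexicons, window: int = 5
) -> tuple[bool, list[dict]]:
    """NegEx-style negation over the sentence's findings.

    A finding is negated when it falls inside the scope of a pre-negation
    phrase (scanning forward) or a post-negation phrase (scanning
    backward).  The scope spans ``window`` tokens, but the counter resets
    at coordinating tokens (',', 'and', 'or') so that a negation
    distributes over a coordinated list of findings, and the scope closes
    at sentence-boundary punctuation.  Pseudo-negation phrases match
    first and block any pre/post phrase they overlap.  Returns
    ``(is_negated, negated_terms)`` where each negated term is a dict
    with token span, surface text and status.
    """
    toks = sentence.lower_tokens
    pseudo = _phrase_matches(toks, lexicons.negation_pseudo)

    def blocked(span):
        return any(not (span[1] <= ps or span[0] >= pe) for ps, pe in pseudo)

    pre = [sp for sp in _phrase_matches(toks, lexicons.negation_pre) if not blocked(sp)]
    post = [sp for sp in _phrase_matches(toks, lexicons.negation_post) if not blocked(sp)]

    scope: set[int] = set()
    for _, pe in pre:
        scope |= _scope_tokens(toks, pe, window, step=+1)
    for ps, _ in post:
        scope |= _scope_tokens(toks, ps - 1, window, step=-1)

    negated = []
    for fs, fe, surface in _findings(sentence, lexicons):
        if any(i in scope for i in range(fs, fe)):
            negated.append({"span": (fs, fe), "text": surface, "status": "negated"})
    return bool(negated), negated


# ---------------------------------------------------------------------------
# protein NER (gazetteer longest-match)


def count_proteins(sentence: Sentence, lexicons: Lexicons) -> int:
    """Count non-overlapping, longest-match gazetteer hits and record the
    resulting mention spans on the sentence."""
    toks = sentence.lower_tokens
    mentions = []
    i = 0
    while i < len(toks):
        hit = None
        for n in range(min(lexicons._max_gaz_len, len(toks) - i), 0, -1):
            if tuple(toks[i : i + n]) in lexicons._gaz_by_len.get(n, ()):
                hit = n
                break
        if hit:
            mentions.append((i, i + hit))
            i += hit
        else:
            i += 1
    sentence.protein_mentions = mentions
    return len(mentions)


# ---------------------------------------------------------------------------
# interactor


def find_interactor(sentence: Sentence, lexicons: Lexicons):
    """Locate the interaction trigger term.

    Every token is stemmed and looked up in the interactor lexicon; the
    selected occurrence is the first match strictly between the leftmost
    and rightmost protein mentions, falling back to the first match
    anywhere.  Returns ``(stemmed_name, pos_tag, character_offset)`` or
    ``(None, None, -1)`` when no token matches.
    """
    matches = [
        (i, stem(tok))
        for i, tok in enumerate(sentence.lower_tokens)
        if stem(tok) in lexicons.interactor_terms
    ]
    covered = {i for s, e in sentence.protein_mentions for i in range(s, e)}
    matches = [(i, s) for i, s in matches if i not in covered]
    if not matches:
        return MISSING, MISSING, -1
    chosen = None
    if len(sentence.protein_mentions) >= 2:
        ms = sorted(sentence.protein_mentions)
        lo, hi = ms[0][1], ms[-1][0]  # gap between outermost mentions
        between = [(i, s) for i, s in matches if lo <= i < hi]
        if between:
            chosen = between[0]
    if chosen is None:
        chosen = matches[0]
    idx, name = chosen
    return name, lexicons.interactor_terms[name], sentence.token_offsets[idx]


# ---------------------------------------------------------------------------
# positional features


def positional_features(sentence: Sentence) -> tuple[int, int, int]:
    """Token counts around the outermost protein mentions.

    Returns ``(n_words_between, n_left_words, n_right_words)``; -1 marks an
    undefined quantity (fewer than two mentions for the between count, no
    tokens on that side otherwise).
    """
    mentions = sorted(sentence.protein_mentions)
    n = len(sentence.tokens)
    if not mentions:
        return -1, -1, -1
    first_start = mentions[0][0]
    last_end = mentions[-1][1]
    n_left = first_start if first_start > 0 else -1
    n_right = n - last_end if n - last_end > 0 else -1
    if len(mentions) >= 2:
        n_between = mentions[-1][0] - mentions[0][1]
    else:
        n_between = -1
    return n_between, n_left, n_right


# ---------------------------------------------------------------------------
# link path


class HeuristicLinkPath:
    """Built-in stand-in for a grammatical link-path check between the two
    outermost protein mentions: a path is reported when an interaction
    trigger term occurs between them and no sentence-boundary punctuation
    ('.' or ';') intervenes."""

    def __init__(self, lexicons: Lexicons):
        self.lexicons = lexicons

    def __call__(self, sentence: Sentence):
        mentions = sorted(sentence.protein_mentions)
        if len(mentions) < 2:
            return MISSING
        lo = mentions[0][1]
        hi = mentions[-1][0]
        inner = sentence.tokens[lo:hi]
        if any(t in {".", ";"} for t in inner):
            return False
        return any(stem(t.lower()) in self.lexicons.interactor_terms for t in inner)


def link_path_status(sentence: Sentence, provider: Callable[[Sentence], bool | None]):
    """Whether a grammatical path links the outermost protein pair.

    Delegates to ``provider``; provider failures are logged and yield
    MISSING rather than propagating.
    """
    if len(sentence.protein_mentions) < 2:
        return MISSING
    try:
        return provider(sentence)
    except Exception:  # pragma: no cover - defensive
        logger.warning("link-path provider failed on sentence %s", sentence.id, exc_info=True)
        return MISSING


# ---------------------------------------------------------------------------
# record + composition


@dataclass(frozen=True)
class FeatureRecord:
    """The nine sentence features."""

    is_negated: bool
    n_protein_occurrences: int
    interactor_name: str | None
    interactor_pos: str | None
    interactor_position: int
    n_words_between: int
    n_left_words: int
    n_right_words: int
    link_path: bool | None

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def extract_features(
    sentence: Sentence,
    lexicons: Lexicons,
    provider: Callable[[Sentence], bool | None] | None = None,
    use_gold_mentions: bool = False,
) -> FeatureRecord:
    """Compose the nine features for one sentence (pure given its inputs).

    With ``use_gold_mentions`` the sentence's existing protein mention
    spans are trusted; otherwise the gazetteer NER runs first.
    """
    if provider is None:
        provider = HeuristicLinkPath(lexicons)
    if use_gold_mentions and sentence.protein_mentions:
        n_prot = len(sentence.protein_mentions)
    else:
        n_prot = count_proteins(sentence, lexicons)
    name, pos, char_off = find_interactor(sentence, lexicons)
    n_between, n_left, n_right = positional_features(sentence)
    is_neg, _ = detect_negation(sentence, lexicons)
    link = link_path_status(sentence, provider)
    return FeatureRecord(
        is_negated=is_neg,
        n_protein_occurrences=n_prot,
        interactor_name=name,
        interactor_pos=pos,
        interactor_position=char_off,
        n_words_between=n_between,
        n_left_words=n_left,
        n_right_words=n_right,
        link_path=link,
    )


# ---------------------------------------------------------------------------
# numeric encoding


def _stable_hash(s: str, buckets: int) -> int:
    return int.from_bytes(hashlib.md5(s.encode("utf-8")).digest()[:4], "big") % buckets


_NUMERIC = ("n_protein_occurrences", "interactor_position", "n_words_between",
            "n_left_words", "n_right_words")


@dataclass
class EncodingSpec:
    """Deterministic numeric encoding of feature records.

    Interactor names are hashed into ``hash_dim`` indicator buckets, the
    POS tag is one-hot over the closed tag set (unknown tags go to OTHER
    with a logged warning), booleans become 0/1 with a missingness
    indicator for the link-path feature, and each count/position becomes a
    z-scored column (statistics fitted on training rows only, sentinels
    excluded) paired with a sentinel indicator column.
    """

    hash_dim: int = 64
    pos_tags: tuple[str, ...] = POS_TAGS
    means_: dict | None = None
    stds_: dict | None = None

    @property
    def column_names(self) -> list[str]:
        cols = ["is_negated"]
        for f in _NUMERIC:
            cols += [f, f + "__undef"]
        cols += [f"interactor_hash_{i}" for i in range(self.hash_dim)]
        cols += ["interactor__missing"]
        cols += [f"pos_{t}" for t in self.pos_tags]
        cols += ["link_path", "link_path__missing"]
        return cols

    def fit(self, records: Sequence[FeatureRecord]) -> "EncodingSpec":
        self.means_, self.stds_ = {}, {}
        for f in _NUMERIC:
            vals = np.array([getattr(r, f) for r in records], dtype=float)
            ok = vals != -1
            self.means_[f] = float(vals[ok].mean()) if ok.any() else 0.0
            sd = float(vals[ok].std()) if ok.any() else 1.0
            self.stds_[f] = sd if sd > 0 else 1.0
        return self

    def transform(self, records: Sequence[FeatureRecord]) -> tuple[np.ndarray, list[str]]:
        if self.means_ is None:
            raise RuntimeError("EncodingSpec must be fitted before transform")
        cols = self.column_names
        X = np.zeros((len(records), len(cols)))
        for i, r in enumerate(records):
            row = {}
            row["is_negated"] = float(r.is_negated)
            for f in _NUMERIC:
                v = getattr(r, f)
                if v == -1:
                    row[f], row[f + "__undef"] = 0.0, 1.0
                else:
                    row[f] = (v - self.means_[f]) / self.stds_[f]
                    row[f + "__undef"] = 0.0
            if r.interactor_name is MISSING:
                row["interactor__missing"] = 1.0
            else:
                row[f"interactor_hash_{_stable_hash(r.interactor_name, self.hash_dim)}"] = 1.0
                pos = r.interactor_pos if r.interactor_pos in self.pos_tags else "OTHER"
                if r.interactor_pos not in self.pos_tags:
                    logger.warning("unknown POS tag %r mapped to OTHER", r.interactor_pos)
                row[f"pos_{pos}"] = 1.0
            if r.link_path is MISSING:
                row["link_path__missing"] = 1.0
            else:
                row["link_path"] = float(r.link_path)
            for j, c in enumerate(cols):
                X[i, j] = row.get(c, 0.0)
        return X, cols


def vectorize(
    records: Sequence[FeatureRecord], spec: EncodingSpec | None = None
) -> tuple[np.ndarray, list[str], EncodingSpec]:
    """Encode records as a numeric matrix.

    An unfitted (or omitted) ``spec`` is fitted on ``records``; a fitted
    spec is applied as-is, so test rows can be encoded with training
    statistics only.
    """
    if spec is None:
        spec = EncodingSpec()
    if spec.means_ is None:
        spec.fit(records)
    X, cols = spec.transform(records)
    return X, cols, spec


# ---------------------------------------------------------------------------
# corpus I/O

_LABEL_TO_STR = {1: "pos", -1: "neg", None: "unk"}
_STR_TO_LABEL = {"pos": 1, "neg": -1, "unk": None}


def read_corpus(path: str | Path) -> list[Sentence]:
    """Read a JSONL corpus (one sentence record per line)."""
    sentences = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        sentences.append(
            Sentence(
                id=str(rec["id"]),
                text=rec["text"],
                protein_mentions=[tuple(sp) for sp in rec.get("proteins", [])],
                label=_STR_TO_LABEL[rec.get("label", "unk")],
            )
        )
    return sentences


def write_corpus(sentences: Iterable[Sentence], path: str | Path) -> None:
    """Write sentences as JSONL with a stable field order."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            rec = {
                "id": s.id,
                "text": s.text,
                "proteins": [list(sp) for sp in s.protein_mentions],
                "label": _LABEL_TO_STR[s.label],
            }
            fh.write(json.dumps(rec) + "\n")


def write_feature_table(records: Sequence[FeatureRecord], path: str | Path) -> None:
    """TSV of the nine named features, one row per sentence."""
    import pandas as pd

    pd.DataFrame([r.as_dict() for r in records], columns=list(FEATURE_NAMES)).to_csv(
        path, sep="\t", index=False
    )
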
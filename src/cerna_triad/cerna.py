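"""ceRNA candidate scoring: shared-miRNA intersection, score and tail test.

A lncRNA and an mRNA are candidate competing endogenous RNAs when they share
miRNA partners. For a candidate pair, with

* ``M_T`` — total number of miRNAs in the universe,
* ``m_p`` — miRNAs paired with the mRNA,
* ``m_n`` — miRNAs paired with the lncRNA,
* ``m_c`` — miRNAs shared by both,

the ceRNA score is the fraction ``m_c / m_n`` of the lncRNA's miRNA partners
that are shared, and significance is the hypergeometric upper tail

    p = sum_{i=m_c}^{min(m_p, m_n)} C(m_n, i) C(M_T - m_n, m_p - i) / C(M_T, m_p),

the probability that two random partner sets of the observed sizes overlap
at least as much as observed. The tail sum is evaluated in log space
(gammaln) so large universes are safe. Candidates supported by sequence
prediction + miRNA correlation are "predicted"; those whose lncRNA-mRNA
expression is itself correlated are "calculated"; the intersection of both
lines of evidence is "shared" — the pairs called as true ceRNAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ConfigError, ValidationError

TARGET_CLASSES = ("mRNA", "lncRNA")


@dataclass(frozen=True)
class TargetPair:
    """One sequence-predicted miRNA -> target relation."""

    mirna_id: str
    target_id: str
    target_class: str
    n_sites: int = 1
    score: float | None = None

    def __post_init__(self) -> None:
        if self.target_class not in TARGET_CLASSES:
            raise ValidationError(f"target_class must be one of {TARGET_CLASSES}")
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna_id, self.target_id)


@dataclass
class CeRNACandidate:
    """One lncRNA-mRNA candidate with its overlap statistics."""

    lncrna_id: str
    mrna_id: str
    M_T: int
    m_p: int
    m_n: int
    m_c: int
    shared_mirna_ids: frozenset = field(default_factory=frozenset)
    cerna_score: float = 0.0
    pval: float = 1.0
    source: str = "predicted"

    def __post_init__(self) -> None:
        if not (0 <= self.m_c <= min(self.m_p, self.m_n) <= max(self.m_p, self.m_n) <= self.M_T):
            raise ValidationError(
                f"inconsistent counts M_T={self.M_T}, m_p={self.m_p}, m_n={self.m_n}, m_c={self.m_c}"
            )
        if len(self.shared_mirna_ids) != self.m_c:
            raise ValidationError("shared_mirna_ids cardinality must equal m_c")

    @property
    def key(self) -> tuple[str, str]:
        return (self.lncrna_id, self.mrna_id)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def dedupe_pairs(pairs) -> list[TargetPair]:
    """Collapse repeated (miRNA, target) predictions, summing site counts."""
    merged: dict[tuple[str, str], TargetPair] = {}
    for p in pairs:
        prev = merged.get(p.key)
        if prev is None:
            merged[p.key] = p
        else:
            merged[p.key] = TargetPair(
                p.mirna_id, p.target_id, p.target_class, prev.n_sites + p.n_sites, prev.score
            )
    return list(merged.values())


def _as_keys(pairs) -> set[tuple[str, str]]:
    keys = set()
    classes = set()
    for p in pairs:
        if isinstance(p, TargetPair):
            keys.add(p.key)
            classes.add(p.target_class)
        elif hasattr(p, "key"):  # e.g. CorrelationEdge, oriented miRNA -> target
            keys.add(p.key)
            if hasattr(p, "target_class"):
                classes.add(p.target_class)
        else:
            keys.add((p[0], p[1]))
    if len(classes) > 1:
        raise ValidationError(f"mixed target classes in one pair set: {sorted(classes)}")
    return keys


def intersect_pairs(predicted, expression_derived) -> set[tuple[str, str]]:
    """Exact intersection of two (miRNA, target) pair sets.

    Accepts :class:`TargetPair` objects (whose target class must be uniform
    within each set) or bare ``(mirna_id, target_id)`` tuples.
    """
    return _as_keys(predicted) & _as_keys(expression_derived)


def cerna_score(m_c: int, m_n: int) -> float:
    """Fraction of the lncRNA's miRNA partners shared with the mRNA."""
    if m_n < 1:
        raise ValidationError("cerna score undefined for m_n = 0")
    if not 0 <= m_c <= m_n:
        raise ValidationError(f"need 0 <= m_c <= m_n, got m_c={m_c}, m_n={m_n}")
    return m_c / m_n


def _log_comb(n: int, k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_pvalue(M_T: int, m_p: int, m_n: int, m_c: int) -> float:
    """Upper-tail probability of sharing >= m_c miRNAs by chance.

    Models the mRNA's ``m_p`` partners as a uniform draw from the ``M_T``
    miRNA universe against the lncRNA's fixed ``m_n`` partners. Exactly 1.0
    at m_c = 0; always in (0, 1].
    """
    for name, v in (("M_T", M_T), ("m_p", m_p), ("m_n", m_n), ("m_c", m_c)):
        if int(v) != v or v < 0:
            raise ValidationError(f"{name} must be a nonnegative integer, got {v}")
    if m_p > M_T or m_n > M_T:
        raise ValidationError("m_p and m_n cannot exceed M_T")
    if m_c > min(m_p, m_n):
        raise ValidationError("m_c cannot exceed min(m_p, m_n)")
    if m_c == 0:
        return 1.0
    lo = max(m_c, m_p + m_n - M_T)
    hi = min(m_p, m_n)
    if lo > hi:
        return 1.0
    i = np.arange(lo, hi + 1)
    log_terms = _log_comb(m_n, i) + _log_comb(M_T - m_n, m_p - i) - _log_comb(M_T, m_p)
    p = float(np.exp(log_terms).sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# candidate calling
# ---------------------------------------------------------------------------

def predict_cernas(
    shared_mirna_mrna_pairs,
    shared_mirna_lncrna_pairs,
    M_T: int | None = None,
    min_shared: int = 1,
    p_threshold: float | None = 0.05,
) -> list[CeRNACandidate]:
    """Score every lncRNA-mRNA pair with >= ``min_shared`` shared miRNAs.

    The two inputs are the evidence-intersected miRNA-mRNA and miRNA-lncRNA
    pair sets (:class:`TargetPair` objects or (miRNA, target) tuples).
    ``M_T`` defaults to the number of distinct miRNAs appearing in either
    set; the study-faithful choice is the number of differentially expressed
    miRNAs in the run. Candidates are kept when ``pval < p_threshold``
    (``None`` keeps all). Output is sorted by (lncRNA, mRNA).
    """
    mrna_keys = _as_keys(shared_mirna_mrna_pairs)
    lncrna_keys = _as_keys(shared_mirna_lncrna_pairs)
    mirnas_of_mrna: dict[str, set[str]] = {}
    for mir, tgt in mrna_keys:
        mirnas_of_mrna.setdefault(tgt, set()).add(mir)
    mirnas_of_lncrna: dict[str, set[str]] = {}
    for mir, tgt in lncrna_keys:
        mirnas_of_lncrna.setdefault(tgt, set()).add(mir)

    universe = {mir for mir, _ in mrna_keys} | {mir for mir, _ in lncrna_keys}
    if M_T is None:
        M_T = len(universe)
    max_partners = max(
        [len(s) for s in mirnas_of_mrna.values()] + [len(s) for s in mirnas_of_lncrna.values()],
        default=0,
    )
    if M_T < max_partners:
        raise ValidationError(f"M_T={M_T} smaller than an observed partner-set size {max_partners}")
    if min_shared < 1:
        raise ConfigError("min_shared must be >= 1")

    out: list[CeRNACandidate] = []
    for lnc, mrna in product(sorted(mirnas_of_lncrna), sorted(mirnas_of_mrna)):
        shared = mirnas_of_lncrna[lnc] & mirnas_of_mrna[mrna]
        if len(shared) < min_shared:
            continue
        m_p = len(mirnas_of_mrna[mrna])
        m_n = len(mirnas_of_lncrna[lnc])
        m_c = len(shared)
        cand = CeRNACandidate(
            lncrna_id=lnc,
            mrna_id=mrna,
            M_T=M_T,
            m_p=m_p,
            m_n=m_n,
            m_c=m_c,
            shared_mirna_ids=frozenset(shared),
            cerna_score=cerna_score(m_c, m_n),
            pval=hypergeom_pvalue(M_T, m_p, m_n, m_c),
            source="predicted",
        )
        if p_threshold is None or cand.pval < p_threshold:
            out.append(cand)
    return out


def call_shared_cernas(predicted, calculated) -> list[CeRNACandidate]:
    """Keep predicted candidates whose pair is also expression co-expressed.

    ``calculated`` holds lncRNA-mRNA :class:`~cerna_triad.correlation.CorrelationEdge`
    objects that survived the co-expression filter (either orientation) or
    bare (lncrna_id, mrna_id) tuples. Kept candidates are re-labelled
    ``source='shared'``; the output is a subset of ``predicted``.
    """
    keys: set[tuple[str, str]] = set()
    for e in calculated:
        if hasattr(e, "source_id"):
            keys.add((e.source_id, e.target_id))
            keys.add((e.target_id, e.source_id))
        else:
            keys.add((e[0], e[1]))
            keys.add((e[1], e[0]))
    out = []
    for c in predicted:
        if c.key in keys:
            kept = CeRNACandidate(
                c.lncrna_id, c.mrna_id, c.M_T, c.m_p, c.m_n, c.m_c,
                c.shared_mirna_ids, c.cerna_score, c.pval, source="shared",
            )
            out.append(kept)
    return out


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

PAIR_COLUMNS = ["mirna_id", "target_id", "target_class", "n_sites", "score"]
CANDIDATE_COLUMNS = [
    "lncrna_id", "mrna_id", "M_T", "m_p", "m_n", "m_c", "cerna_score", "pval", "shared_mirnas", "source",
]


def write_target_pairs(pairs, path) -> None:
    pd.DataFrame([vars(p) for p in pairs], columns=PAIR_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_target_pairs(path) -> list[TargetPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        TargetPair(
            str(r.mirna_id), str(r.target_id), r.target_class, int(r.n_sites),
            None if pd.isna(r.score) else float(r.score),
        )
        for r in df.itertuples()
    ]


def candidates_to_frame(cands) -> pd.DataFrame:
    rows = [
        {
            "lncrna_id": c.lncrna_id,
            "mrna_id": c.mrna_id,
            "M_T": c.M_T,
            "m_p": c.m_p,
            "m_n": c.m_n,
            "m_c": c.m_c,
            "cerna_score": c.cerna_score,
            "pval": c.pval,
            "shared_mirnas": ",".join(sorted(c.shared_mirna_ids)),
            "source": c.source,
        }
        for c in cands
    ]
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def write_candidates(cands, path) -> None:
    candidates_to_frame(cands).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_candidates(path) -> list[CeRNACandidate]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    out = []
    for r in df.itertuples():
        shared = frozenset(str(r.shared_mirnas).split(",")) if r.shared_mirnas else frozenset()
        out.append(
            CeRNACandidate(
                str(r.lncrna_id), str(r.mrna_id), int(r.M_T), int(r.m_p), int(r.m_n), int(r.m_c),
                shared, float(r.cerna_score), float(r.pval), str(r.source),
            )
        )
    return out
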
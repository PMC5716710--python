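"""Pearson correlation of expression profiles and the sign/threshold filters.

Candidate miRNA-target pairs are kept when they are *negatively* correlated
beyond a coefficient threshold with a small two-sided p-value; lncRNA-mRNA
co-expression uses the same machinery with a positive (or absolute) sign
convention. All samples from both groups are pooled: with three replicates
per phase the correlations run on n = 6 points, where |r| = 0.7 alone has a
two-sided p of about 0.12 — the p < 0.05 condition is therefore strictly
stronger than the coefficient cut, and both are applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateInputError, ValidationError
from .quant import ExpressionMatrix, LOG_PSEUDOCOUNT

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationEdge:
    """One expression-derived pair with its Pearson statistics."""

    source_id: str
    target_id: str
    source_class: str
    target_class: str
    r: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValidationError("correlation edge needs n >= 3")
        if not -1.0 <= self.r <= 1.0:
            raise ValidationError(f"|r| must be <= 1, got {self.r}")
        if (self.source_id, self.source_class) == (self.target_id, self.target_class):
            raise ValidationError(f"self-edge on {self.source_id}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.source_id, self.target_id)


def pearson(x, y) -> tuple[float, float, int]:
    """Sample Pearson r with its two-sided p-value.

    The p-value is the classical t transform, ``t = r*sqrt(n-2)/sqrt(1-r^2)``
    on n-2 degrees of freedom (scipy's exact beta form is identical);
    r = +/-1 gives p = 0. Constant input raises
    :class:`DegenerateInputError` — callers drop such pairs with a log entry.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValidationError("pearson requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    p = 0.0 if abs(r) == 1.0 else float(res.pvalue)
    return r, p, n


def correlate_classes(
    m: ExpressionMatrix,
    class_a: str,
    class_b: str,
    restrict_to=None,
    log_transform: bool = True,
    pseudocount: float = LOG_PSEUDOCOUNT,
) -> list[CorrelationEdge]:
    """Correlate every (class_a, class_b) feature pair across pooled samples.

    ``restrict_to`` limits evaluation to an explicit (a_id, b_id) pair list —
    used to stay inside the sequence-predicted pair universe. By default the
    profiles are log2(value + pseudocount)-transformed first. Pairs with a
    constant profile are skipped with a logged warning.
    """
    a_ids = m.features_of_class(class_a)
    b_ids = m.features_of_class(class_b)
    if not a_ids or not b_ids:
        raise ValidationError(f"no features of class {class_a if not a_ids else class_b!r}")
    vals = m.values
    if log_transform:
        vals = np.log2(vals + pseudocount)

    if restrict_to is None:
        pairs = [(a, b) for a in a_ids for b in b_ids if a != b]
    else:
        known_a, known_b = set(a_ids), set(b_ids)
        pairs = [(a, b) for a, b in restrict_to if a in known_a and b in known_b]

    edges: list[CorrelationEdge] = []
    dropped = 0
    for a, b in pairs:
        try:
            r, p, n = pearson(vals.loc[a], vals.loc[b])
        except DegenerateInputError:
            dropped += 1
            continue
        edges.append(CorrelationEdge(a, b, class_a, class_b, r, p, n))
    if dropped:
        logger.warning("dropped %d constant-profile pair(s) from %s-%s correlation", dropped, class_a, class_b)
    return edges


def filter_negative(edges, r_threshold: float = 0.7, p_threshold: float = 0.05) -> list[CorrelationEdge]:
    """Keep negatively correlated edges: r < -r_threshold and p < p_threshold
    (both strict)."""
    _check_thresholds(r_threshold, p_threshold)
    return [e for e in edges if e.r < -r_threshold and e.pval < p_threshold]


def filter_coexpressed(
    edges, r_threshold: float = 0.7, p_threshold: float = 0.05, mode: str = "absolute"
) -> list[CorrelationEdge]:
    """Keep co-expressed edges.

    ``mode='positive'`` keeps r > r_threshold; ``mode='absolute'`` (default)
    keeps |r| > r_threshold — competing pairs are observed in both
    orientations. p < p_threshold in either mode.
    """
    _check_thresholds(r_threshold, p_threshold)
    if mode == "positive":
        return [e for e in edges if e.r > r_threshold and e.pval < p_threshold]
    if mode == "absolute":
        return [e for e in edges if abs(e.r) > r_threshold and e.pval < p_threshold]
    raise ConfigError(f"unknown co-expression mode {mode!r} (use 'positive' or 'absolute')")


def _check_thresholds(r_threshold: float, p_threshold: float) -> None:
    if not 0 < r_threshold < 1:
        raise ConfigError("r_threshold must be in (0, 1)")
    if not 0 < p_threshold < 1:
        raise ConfigError("p_threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ["source_id", "target_id", "source_class", "target_class", "r", "pval", "n"]


def edges_to_frame(edges) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in edges], columns=EDGE_COLUMNS)


def write_edges(edges, path) -> None:
    edges_to_frame(edges).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edges(path) -> list[CorrelationEdge]:
    df = pd.read_csv(path, sep="\t")
    return [
        CorrelationEdge(
            str(row.source_id), str(row.target_id), row.source_class, row.target_class,
            float(row.r), float(row.pval), int(row.n),
        )
        for row in df.itertuples()
    ]
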
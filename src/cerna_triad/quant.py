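"""Expression matrices, RPKM/TPM quantification and differential classification.

The central container is :class:`ExpressionMatrix`, a feature-by-sample table
of nonnegative abundances in which every feature carries an RNA class
(``mRNA``, ``miRNA`` or ``lncRNA``) and every sample a group label
(``control`` for the early/basal phase, ``treatment`` for the later phase).
Gene and lncRNA abundances are normalised as RPKM (reads per kilobase of
transcript model per million mapped reads); miRNA abundances as TPM
(transcripts per million, no length normalisation).

Differential classification follows the two-group design of the study this
package emulates: fold change is the treatment/control mean ratio, features
with a zero control mean are reported as ``inf`` (and ``-inf`` for a zero
treatment mean), and significance comes from Welch's t-test on
log2(value + pseudocount) across replicates with Benjamini-Hochberg
adjustment within each RNA class.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ParseError, ValidationError

logger = logging.getLogger(__name__)

RNA_CLASSES = ("mRNA", "miRNA", "lncRNA")
GROUPS = ("control", "treatment")

#: default pseudocount added before log2 when testing group differences
LOG_PSEUDOCOUNT = 1e-2


@dataclass
class ExpressionMatrix:
    """Feature-by-sample abundance table with class and group annotations.

    Parameters
    ----------
    values
        DataFrame of nonnegative abundances, index = feature ids,
        columns = sample ids.
    feature_class
        Series mapping feature id -> RNA class (one of ``RNA_CLASSES``).
    groups
        Series mapping sample id -> group (one of ``GROUPS``).
    feature_length
        Optional Series of positive transcript lengths (nt); required only
        for RPKM / length-normalised TPM.
    """

    values: pd.DataFrame
    feature_class: pd.Series
    groups: pd.Series
    feature_length: pd.Series | None = None

    def __post_init__(self) -> None:
        self.feature_class = pd.Series(self.feature_class).reindex(self.values.index)
        self.groups = pd.Series(self.groups).reindex(self.values.columns)
        if self.feature_length is not None:
            self.feature_length = pd.Series(self.feature_length).reindex(self.values.index)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate feature ids: {dups}")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be nonnegative")
        bad = set(self.feature_class.dropna()) - set(RNA_CLASSES)
        if bad or self.feature_class.isna().any():
            raise ValidationError(f"feature classes must be one of {RNA_CLASSES}, got {bad or 'missing'}")
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValidationError(f"samples with no group assignment: {missing}")
        bad_g = set(self.groups) - set(GROUPS)
        if bad_g:
            raise ValidationError(f"groups must be one of {GROUPS}, got {sorted(bad_g)}")
        if self.feature_length is not None:
            if self.feature_length.isna().any() or (self.feature_length <= 0).any():
                raise ValidationError("feature lengths must be positive where present")

    # -- convenience -----------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def features_of_class(self, rna_class: str) -> list[str]:
        return list(self.feature_class.index[self.feature_class == rna_class])

    def subset_features(self, ids) -> "ExpressionMatrix":
        ids = list(ids)
        return ExpressionMatrix(
            values=self.values.loc[ids],
            feature_class=self.feature_class.loc[ids],
            groups=self.groups,
            feature_length=None if self.feature_length is None else self.feature_length.loc[ids],
        )

    def equals(self, other: "ExpressionMatrix") -> bool:
        same_len = (
            (self.feature_length is None and other.feature_length is None)
            or (
                self.feature_length is not None
                and other.feature_length is not None
                and self.feature_length.equals(other.feature_length)
            )
        )
        return (
            self.values.equals(other.values)
            and self.feature_class.equals(other.feature_class)
            and self.groups.equals(other.groups)
            and same_len
        )


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def read_expression(path, groups) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    Expected layout: header row ``feature_id  class  [length]  <sample...>``;
    one row per feature. ``groups`` is either a path to a two-column TSV
    (``sample_id  group``) or a mapping sample id -> group.

    Raises
    ------
    ParseError
        On duplicate ids, negative values or a missing group assignment,
        citing the offending line where possible.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "feature_id" or df.columns[1] != "class":
        raise ParseError(f"{path}: expected leading columns 'feature_id', 'class'", line=1)
    has_length = len(df.columns) > 2 and df.columns[2] == "length"
    meta_cols = 3 if has_length else 2
    sample_cols = list(df.columns[meta_cols:])
    if not sample_cols:
        raise ParseError(f"{path}: no sample columns found", line=1)

    ids = df["feature_id"]
    dup_mask = ids.duplicated()
    if dup_mask.any():
        row = int(np.flatnonzero(dup_mask.to_numpy())[0])
        raise ParseError(f"{path}: duplicate feature id {ids.iloc[row]!r}", line=row + 2)
    vals = df[sample_cols].apply(pd.to_numeric)
    neg = vals.lt(0).any(axis=1)
    if neg.any():
        row = int(np.flatnonzero(neg.to_numpy())[0])
        raise ParseError(f"{path}: negative expression value for {ids.iloc[row]!r}", line=row + 2)

    group_map = read_group_map(groups) if not isinstance(groups, (dict, pd.Series)) else pd.Series(groups)
    missing = [s for s in sample_cols if s not in group_map.index]
    if missing:
        raise ParseError(f"{path}: samples with no group mapping: {missing}", line=1)

    values = vals.set_axis(ids.to_numpy(), axis=0)
    values.index.name = None
    try:
        return ExpressionMatrix(
            values=values,
            feature_class=pd.Series(df["class"].to_numpy(), index=values.index),
            groups=group_map.loc[sample_cols],
            feature_length=(
                pd.Series(pd.to_numeric(df["length"]).to_numpy(), index=values.index) if has_length else None
            ),
        )
    except ValidationError as exc:  # re-raise with file context
        raise ParseError(f"{path}: {exc}") from exc


def read_group_map(path) -> pd.Series:
    gm = pd.read_csv(path, sep="\t", dtype=str)
    if list(gm.columns[:2]) != ["sample_id", "group"]:
        raise ParseError(f"{path}: expected columns 'sample_id', 'group'", line=1)
    return pd.Series(gm["group"].to_numpy(), index=gm["sample_id"].to_numpy())


def write_expression(m: ExpressionMatrix, path, groups_path=None) -> None:
    """Write the matrix (and optionally its group map) as TSV; round-trips
    through :func:`read_expression`."""
    out = pd.DataFrame({"feature_id": m.feature_ids, "class": m.feature_class.to_numpy()})
    if m.feature_length is not None:
        out["length"] = m.feature_length.to_numpy()
    out = pd.concat([out.reset_index(drop=True), m.values.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)
    if groups_path is not None:
        pd.DataFrame({"sample_id": m.sample_ids, "group": m.groups.to_numpy()}).to_csv(
            groups_path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def compute_rpkm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Reads per kilobase per million mapped reads.

    ``rpkm[i, j] = count[i, j] * 1e9 / (length[i] * column_total[j])``.
    Requires feature lengths; input values are raw counts.
    """
    if m.feature_length is None:
        raise ValidationError("RPKM requires feature lengths")
    totals = m.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"zero column total for sample(s) {list(zero.index)}")
    rpkm = m.values.mul(1e9).div(m.feature_length, axis=0).div(totals, axis=1)
    return ExpressionMatrix(rpkm, m.feature_class, m.groups, m.feature_length)


def compute_tpm(m: ExpressionMatrix, length_normalize: bool = False) -> ExpressionMatrix:
    """Transcripts per million; every column sums to 1e6.

    For miRNA counts (the default use here) the per-feature rate is the raw
    count; with ``length_normalize=True`` the rate is count/length, the
    standard TPM for long transcripts.
    """
    if length_normalize:
        if m.feature_length is None:
            raise ValidationError("length-normalised TPM requires feature lengths")
        rate = m.values.div(m.feature_length, axis=0)
    else:
        rate = m.values
    totals = rate.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"zero column total for sample(s) {list(zero.index)}")
    tpm = rate.mul(1e6).div(totals, axis=1)
    return ExpressionMatrix(tpm, m.feature_class, m.groups, m.feature_length)


# ---------------------------------------------------------------------------
# fold change and differential classification
# ---------------------------------------------------------------------------

def fold_change(treat_mean: float, control_mean: float) -> tuple[float, float]:
    """(fold change, log2 fold change) for a treatment/control mean pair.

    Zero control mean gives ``(inf, inf)``; zero treatment mean ``(0, -inf)``;
    both zero is undefined and raises.
    """
    if treat_mean < 0 or control_mean < 0:
        raise ValidationError("group means must be nonnegative")
    if treat_mean == 0 and control_mean == 0:
        raise ValidationError("fold change undefined: both group means are zero")
    if control_mean == 0:
        return math.inf, math.inf
    fc = treat_mean / control_mean
    return fc, (-math.inf if fc == 0 else math.log2(fc))


def classify_direction(
    fc: float, pval: float, fc_threshold: float | None = 2.0, alpha: float = 0.05
) -> str:
    """Classify one feature as Up / Down / NotSignificant.

    ``fc_threshold`` is the symmetric fold-change gate (Up needs
    fc >= threshold, Down needs fc <= 1/threshold); ``None`` disables the
    gate and direction follows the sign of the fold change alone, which is
    the rule the reference tables this package ships actually obey.
    Significance requires ``pval < alpha`` (strict). A missing p (NaN) is
    never significant.
    """
    if fc_threshold is not None and fc_threshold <= 1:
        raise ConfigError("fc_threshold must be > 1 (or None to disable the gate)")
    if not (pval < alpha):  # NaN-safe: NaN comparisons are False
        return "NotSignificant"
    if fc_threshold is None:
        if fc > 1:
            return "Up"
        if fc < 1:
            return "Down"
        return "NotSignificant"
    if fc >= fc_threshold:
        return "Up"
    if fc <= 1.0 / fc_threshold:
        return "Down"
    return "NotSignificant"


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (NaNs propagate)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def classify_differential(
    table: pd.DataFrame,
    fc_threshold: float | None = 2.0,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Apply the direction rule to a table with ``foldChange``/``pval``
    (and optionally ``padj``) columns, adding a ``direction`` column.

    Used both on computed differential tables and on transcribed published
    tables where fold changes and p-values are data.
    """
    col = "padj" if use_adjusted else "pval"
    if col not in table.columns:
        raise ConfigError(f"table has no {col!r} column")
    out = table.copy()
    out["direction"] = [
        classify_direction(fc, p, fc_threshold=fc_threshold, alpha=alpha)
        for fc, p in zip(out["foldChange"], out[col])
    ]
    return out


def differential_table(
    m: ExpressionMatrix,
    fc_threshold: float | None = 2.0,
    alpha: float = 0.05,
    use_adjusted: bool = False,
    pseudocount: float = LOG_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-feature differential table for a two-group matrix.

    Columns: ``feature_id class foldChange log2FoldChange pval padj
    direction``. Fold change is mean(treatment)/mean(control); p-values are
    Welch's t on log2(value + pseudocount) across replicates; ``padj`` is
    Benjamini-Hochberg within each RNA class. With fewer than two replicates
    per group the p-values are NaN (with a warning) and nothing is called
    significant.
    """
    ctrl = m.samples_in_group("control")
    treat = m.samples_in_group("treatment")
    if not ctrl or not treat:
        raise ValidationError("both groups must be present")
    cvals = m.values[ctrl].to_numpy(dtype=float)
    tvals = m.values[treat].to_numpy(dtype=float)
    cmean = cvals.mean(axis=1)
    tmean = tvals.mean(axis=1)

    fcs, l2fcs = [], []
    for tm, cm in zip(tmean, cmean):
        if tm == 0 and cm == 0:
            fcs.append(np.nan)
            l2fcs.append(np.nan)
        else:
            fc, l2 = fold_change(tm, cm)
            fcs.append(fc)
            l2fcs.append(l2)

    if len(ctrl) < 2 or len(treat) < 2:
        warnings.warn("fewer than 2 replicates per group: p-values omitted", stacklevel=2)
        pvals = np.full(len(m.feature_ids), np.nan)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(
                np.log2(tvals + pseudocount), np.log2(cvals + pseudocount), axis=1, equal_var=False
            )
        pvals = np.asarray(res.pvalue, dtype=float)
        # zero variance in both groups with equal means -> no evidence
        pvals[np.isnan(pvals)] = 1.0
        pvals[np.isnan(np.array(fcs))] = np.nan  # both-zero features stay uncalled

    out = pd.DataFrame(
        {
            "feature_id": m.feature_ids,
            "class": m.feature_class.to_numpy(),
            "foldChange": fcs,
            "log2FoldChange": l2fcs,
            "pval": pvals,
        }
    )
    out["padj"] = np.nan
    for cls in out["class"].unique():
        sel = out["class"] == cls
        out.loc[sel, "padj"] = bh_adjust(out.loc[sel, "pval"].to_numpy())
    return classify_differential(out, fc_threshold=fc_threshold, alpha=alpha, use_adjusted=use_adjusted)


def write_differential(table: pd.DataFrame, path) -> None:
    """Write a differential table as TSV with ``Inf``/``-Inf`` literals,
    mirroring the published table layout (``up_down`` column name)."""
    out = table.rename(columns={"direction": "up_down"})
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_differential(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns={"up_down": "direction"})
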
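"""Synthetic two-group, three-class expression data with planted ceRNA triplets.

The generator emulates the study design the pipeline expects: two lactation
phases with three replicates each, and three RNA classes measured on the
same samples. A planted ceRNA "triplet" is a (miRNA set, mRNA, lncRNA)
regulatory unit: the miRNAs shift between groups by a configurable fold
change and repress both the mRNA and the lncRNA, so that planted
miRNA-target pairs are negatively correlated, the lncRNA-mRNA pair is
positively correlated, and all planted features are differentially
expressed. The matching sequence-predicted pair list contains every planted
(miRNA, target) pair plus random decoy pairs with no expression coupling,
giving the correlation filter something to reject.

Expression model (all draws from one seeded generator):

* per-feature baseline ``b_i`` ~ log-normal(log(baseline_mean), baseline_sigma);
* miRNA ``m`` in sample ``j``: ``b_m * FC^[planted & treatment] * exp(noise_sd * z)``;
* planted target: ``b_t * prod_m (x_mj / gmean_j(x_mj))^(-repression_strength)
  * exp(noise_sd * z)`` over its regulating miRNAs ``m``;
* decoy target: ``b_t * exp(noise_sd * z)``.

At ``noise_sd = 0`` and ``repression_strength = 1`` the construction is
exactly anti-monotone: planted miRNA-target correlations are -1 and planted
lncRNA-mRNA correlations +1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .cerna import TargetPair
from .errors import ConfigError, ValidationError
from .quant import ExpressionMatrix


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the emulated design: 3 replicates per phase, 20 miRNAs,
    200 mRNAs, 50 lncRNAs, 5 planted triplets each sharing 3 miRNAs, a
    4-fold miRNA shift between phases, log-scale noise sd 0.1 and a 5%
    decoy-pair rate in the predicted list.
    """

    n_samples_per_group: int = 3
    n_mirna: int = 20
    n_mrna: int = 200
    n_lncrna: int = 50
    n_planted_triplets: int = 5
    mirnas_per_triplet: int = 3
    mirna_fold_change: float = 4.0
    repression_strength: float = 0.8
    noise_sd: float = 0.1
    baseline_mean: float = 100.0
    baseline_sigma: float = 1.0
    extra_mre_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples_per_group", "n_mirna", "n_mrna", "n_lncrna", "n_planted_triplets",
                     "mirnas_per_triplet"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_planted_triplets > min(self.n_mrna, self.n_lncrna):
            raise ConfigError("n_planted_triplets exceeds available mRNAs or lncRNAs")
        if self.n_planted_triplets * self.mirnas_per_triplet > self.n_mirna:
            raise ConfigError("n_planted_triplets * mirnas_per_triplet exceeds n_mirna")
        if self.mirna_fold_change <= 0:
            raise ConfigError("mirna_fold_change must be positive")
        if not 0 <= self.repression_strength <= 1:
            raise ConfigError("repression_strength must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be positive")
        if self.baseline_sigma < 0:
            raise ConfigError("baseline_sigma must be nonnegative")
        if not 0 <= self.extra_mre_rate <= 1:
            raise ConfigError("extra_mre_rate must be in [0, 1]")

    @classmethod
    def from_mapping(cls, mapping) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown simulation field(s): {sorted(unknown)}")
        cfg = cls(**{k: type(getattr(cls, k))(v) for k, v in mapping.items()})
        cfg.validate()
        return cfg


@dataclass
class SyntheticTruth:
    """Ground truth for one generated dataset.

    ``planted_triplets`` lists one (miRNA, mRNA, lncRNA) triple per planted
    regulatory relation — a triplet unit sharing k miRNAs contributes k
    triples with the same (mRNA, lncRNA). ``planted_pair_list`` holds the
    corresponding predicted-pair records (a subset of the emitted pair list).
    """

    planted_triplets: list[tuple[str, str, str]]
    planted_pair_list: list[TargetPair]
    mirna_ids: list[str] = field(default_factory=list)
    mrna_ids: list[str] = field(default_factory=list)
    lncrna_ids: list[str] = field(default_factory=list)

    @property
    def planted_cerna_pairs(self) -> set[tuple[str, str]]:
        """Unique planted (lncRNA, mRNA) pairs."""
        return {(lnc, mrna) for _, mrna, lnc in self.planted_triplets}


def generate_dataset(config: SimulationConfig) -> tuple[ExpressionMatrix, list[TargetPair], SyntheticTruth]:
    """Generate (expression matrix, predicted pair list, ground truth).

    Deterministic: the same config (including seed) reproduces byte-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_per = config.n_samples_per_group
    n_samples = 2 * n_per

    mir_ids = [f"miR-{i + 1:03d}" for i in range(config.n_mirna)]
    mrna_ids = [f"mRNA-{i + 1:03d}" for i in range(config.n_mrna)]
    lnc_ids = [f"lnc-{i + 1:03d}" for i in range(config.n_lncrna)]
    sample_ids = [f"ctrl_{j + 1}" for j in range(n_per)] + [f"treat_{j + 1}" for j in range(n_per)]
    groups = pd.Series(["control"] * n_per + ["treatment"] * n_per, index=sample_ids)
    treat_mask = np.array([0.0] * n_per + [1.0] * n_per)

    mu = np.log(config.baseline_mean)
    base_mir = np.exp(rng.normal(mu, config.baseline_sigma, config.n_mirna))
    base_mrna = np.exp(rng.normal(mu, config.baseline_sigma, config.n_mrna))
    base_lnc = np.exp(rng.normal(mu, config.baseline_sigma, config.n_lncrna))

    k = config.mirnas_per_triplet
    triplet_mirs = [list(range(t * k, (t + 1) * k)) for t in range(config.n_planted_triplets)]

    def noise(shape):
        if config.noise_sd == 0:
            return np.ones(shape)
        return np.exp(rng.normal(0.0, config.noise_sd, shape))

    # miRNAs: planted ones shift by mirna_fold_change in the treatment group
    planted_mir = np.zeros(config.n_mirna, dtype=bool)
    for mirs in triplet_mirs:
        planted_mir[mirs] = True
    group_effect = np.where(
        planted_mir[:, None], config.mirna_fold_change ** treat_mask[None, :], 1.0
    )
    mir_vals = base_mir[:, None] * group_effect * noise((config.n_mirna, n_samples))

    # targets: planted ones track their miRNAs' relative abundance
    def target_matrix(base, n_feat, planted_map):
        vals = base[:, None] * noise((n_feat, n_samples))
        for feat_idx, mirs in planted_map.items():
            rel = mir_vals[mirs, :] / gmean(mir_vals[mirs, :], axis=1)[:, None]
            repression = np.prod(rel ** (-config.repression_strength), axis=0)
            vals[feat_idx, :] = base[feat_idx] * repression * noise(n_samples)
        return vals

    mrna_map = {t: mirs for t, mirs in enumerate(triplet_mirs)}
    lnc_map = {t: mirs for t, mirs in enumerate(triplet_mirs)}
    mrna_vals = target_matrix(base_mrna, config.n_mrna, mrna_map)
    lnc_vals = target_matrix(base_lnc, config.n_lncrna, lnc_map)

    values = pd.DataFrame(
        np.vstack([mir_vals, mrna_vals, lnc_vals]),
        index=mir_ids + mrna_ids + lnc_ids,
        columns=sample_ids,
    )
    feature_class = pd.Series(
        ["miRNA"] * config.n_mirna + ["mRNA"] * config.n_mrna + ["lncRNA"] * config.n_lncrna,
        index=values.index,
    )
    matrix = ExpressionMatrix(values=values, feature_class=feature_class, groups=groups)

    # predicted pair list: planted pairs first, then uniform decoy pairs
    planted_pairs: list[TargetPair] = []
    planted_keys: set[tuple[str, str]] = set()
    triplets: list[tuple[str, str, str]] = []
    for t, mirs in enumerate(triplet_mirs):
        for m in mirs:
            triplets.append((mir_ids[m], mrna_ids[t], lnc_ids[t]))
            for tgt, cls in ((mrna_ids[t], "mRNA"), (lnc_ids[t], "lncRNA")):
                pair = TargetPair(mir_ids[m], tgt, cls, n_sites=int(rng.integers(1, 4)))
                planted_pairs.append(pair)
                planted_keys.add(pair.key)

    pair_list = list(planted_pairs)
    for tgt_ids, cls in ((mrna_ids, "mRNA"), (lnc_ids, "lncRNA")):
        hits = rng.random((config.n_mirna, len(tgt_ids))) < config.extra_mre_rate
        for mi, ti in zip(*np.nonzero(hits)):
            key = (mir_ids[mi], tgt_ids[ti])
            if key not in planted_keys:
                pair_list.append(TargetPair(key[0], key[1], cls, n_sites=1))

    truth = SyntheticTruth(
        planted_triplets=triplets,
        planted_pair_list=planted_pairs,
        mirna_ids=mir_ids,
        mrna_ids=mrna_ids,
        lncrna_ids=lnc_ids,
    )
    return matrix, pair_list, truth


def truth_confusion(called, truth: SyntheticTruth) -> tuple[float, float]:
    """Precision and recall of called lncRNA-mRNA pairs against the truth.

    ``called`` holds CeRNACandidate objects or (lncrna_id, mrna_id) tuples.
    Precision is defined as 1.0 for an empty call set. Ids outside the
    truth's universe raise a ValidationError listing them.
    """
    called_keys = {c.key if hasattr(c, "key") else (c[0], c[1]) for c in called}
    lnc_universe = set(truth.lncrna_ids)
    mrna_universe = set(truth.mrna_ids)
    unknown = sorted(
        {lnc for lnc, _ in called_keys if lnc not in lnc_universe}
        | {mrna for _, mrna in called_keys if mrna not in mrna_universe}
    )
    if unknown:
        raise ValidationError(f"called pairs reference unknown ids: {unknown}")
    planted = truth.planted_cerna_pairs
    tp = len(called_keys & planted)
    precision = 1.0 if not called_keys else tp / len(called_keys)
    recall = 1.0 if not planted else tp / len(planted)
    return precision, recall


def write_truth(truth: SyntheticTruth, path) -> None:
    """Tab-delimited triplet table: ``mirna_id  mrna_id  lncrna_id``."""
    pd.DataFrame(truth.planted_triplets, columns=["mirna_id", "mrna_id", "lncrna_id"]).to_csv(
        path, sep="\t", index=False
    )
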
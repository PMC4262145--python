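"""Decoy-set evaluation: native recognition, best-model selection,
energy-quality correlation, and near-native classification.

A target is one native structure plus its decoy models, each with an energy
and an externally computed quality score (TM-score in (0, 1]).  Metrics:

* native rank and Z-score: Z = (E_native - <E_decoy>) / sd(E_decoy), with
  the population standard deviation over decoys (native excluded);
* logP_B1 / logP_B10: log probability that the lowest-energy model (or one
  of the 10 lowest) is the best-quality model — ln(min_{i<=k} R_i / n)
  where R_i is the quality rank of the i-th lowest-energy of n decoys;
* Pearson r and Kendall tau-b between energy and quality;
* ROC AUC for classifying near-native models (quality > 0.5), lower energy
  treated as more positive, computed as the normalized Mann-Whitney U.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DecoyRecord",
    "TargetSet",
    "DegenerateTargetError",
    "native_rank",
    "zscore",
    "log_pb",
    "correlations",
    "roc_auc",
    "paired_ttest",
    "evaluate_suite",
    "read_manifest",
]


class DegenerateTargetError(ValueError):
    """Metric undefined for this target (no spread, no native, too few)."""


@dataclass(frozen=True)
class DecoyRecord:
    model_id: str
    energy: float
    quality: float | None = None  # TM-score in (0, 1]
    is_native: bool = False

    def __post_init__(self):
        if not math.isfinite(self.energy):
            raise ValueError(f"{self.model_id}: non-finite energy")
        if self.quality is not None and not 0.0 < self.quality <= 1.0:
            raise ValueError(f"{self.model_id}: quality outside (0, 1]")


@dataclass
class TargetSet:
    target_id: str
    records: list[DecoyRecord] = field(default_factory=list)
    decoy_set: str = ""

    @property
    def native(self) -> DecoyRecord:
        natives = [r for r in self.records if r.is_native]
        if len(natives) != 1:
            raise DegenerateTargetError(
                f"{self.target_id}: expected exactly one native, "
                f"found {len(natives)}")
        return natives[0]

    @property
    def decoys(self) -> list[DecoyRecord]:
        return [r for r in self.records if not r.is_native]


def native_rank(target: TargetSet) -> int:
    """Energy rank of the native (1 = lowest); ties counted pessimistically,
    so a native tied with k decoys ranks 1 + k."""
    e_native = target.native.energy
    return 1 + sum(1 for r in target.decoys if r.energy <= e_native)


def zscore(target: TargetSet) -> float:
    decoy_e = np.array([r.energy for r in target.decoys])
    if len(decoy_e) < 2:
        raise DegenerateTargetError(f"{target.target_id}: fewer than 2 decoys")
    sd = float(decoy_e.std())  # population sd
    if sd == 0.0:
        raise DegenerateTargetError(f"{target.target_id}: zero energy spread")
    return float((target.native.energy - decoy_e.mean()) / sd)


def _decoy_arrays(target: TargetSet, require_quality: bool = True):
    decoys = target.decoys
    if require_quality and any(r.quality is None for r in decoys):
        raise DegenerateTargetError(f"{target.target_id}: missing quality")
    energy = np.array([r.energy for r in decoys])
    quality = np.array([r.quality for r in decoys], dtype=float)
    return energy, quality


def log_pb(target: TargetSet, k: int = 1, base: str = "e") -> float:
    """ln (or log10, base="10") of the probability of having selected the
    best-quality model within the k lowest-energy ones; native excluded."""
    energy, quality = _decoy_arrays(target)
    n = len(energy)
    if n < k:
        raise DegenerateTargetError(f"{target.target_id}: n={n} < k={k}")
    quality_rank = stats.rankdata(-quality, method="min")  # 1 = best quality
    by_energy = np.argsort(energy, kind="stable")
    best = int(quality_rank[by_energy[:k]].min())
    log = math.log10 if base == "10" else math.log
    return log(best / n)


def correlations(target: TargetSet, include_native: bool = False):
    """(Pearson r, Kendall tau-b) between energy and quality.

    Raises DegenerateTargetError when either variable has no variance.
    The native (quality 1.0) can be included or excluded.
    """
    if include_native:
        records = target.records
        energy = np.array([r.energy for r in records])
        quality = np.array([1.0 if r.is_native else r.quality
                            for r in records], dtype=float)
        if np.any(np.isnan(quality)):
            raise DegenerateTargetError(f"{target.target_id}: missing quality")
    else:
        energy, quality = _decoy_arrays(target)
    if len(energy) < 3 or energy.std() == 0 or quality.std() == 0:
        raise DegenerateTargetError(f"{target.target_id}: degenerate correlation")
    r = float(stats.pearsonr(energy, quality).statistic)
    tau = float(stats.kendalltau(energy, quality, variant="b").statistic)
    return r, tau


def roc_auc(target: TargetSet, threshold: float = 0.5,
            min_positives: int = 10) -> float:
    """AUC for near-native (quality > threshold) vs non-native decoys, with
    lower energy more positive; equals the normalized Mann-Whitney U with
    ties contributing 1/2.  Native excluded; requires more than
    min_positives positives and at least one negative."""
    energy, quality = _decoy_arrays(target)
    labels = quality > threshold
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos <= min_positives or n_neg < 1:
        raise DegenerateTargetError(
            f"{target.target_id}: {n_pos} positives / {n_neg} negatives")
    ranks = stats.rankdata(-energy)  # higher rank = lower energy = more positive
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def paired_ttest(auc_a, auc_b) -> float:
    """Two-sided paired t-test p-value over per-target AUC differences."""
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired AUC lists must be equal-length, n >= 2")
    diff = a - b
    if np.allclose(diff.std(), 0.0):
        raise DegenerateTargetError("zero-variance differences")
    return float(stats.ttest_rel(a, b).pvalue)


def evaluate_suite(targets, tm_threshold: float = 0.5,
                   min_positives: int = 10) -> dict:
    """All metrics per target, aggregated per decoy set and overall.

    Returns {"per_target": DataFrame, "summary": DataFrame,
    "skipped": list of (target_id, metric, reason)}.  Metrics that are
    undefined for a target are reported as NaN and listed in "skipped".
    """
    rows = []
    skipped: list[tuple[str, str, str]] = []

    def attempt(tid, name, fn):
        try:
            return fn()
        except DegenerateTargetError as exc:
            skipped.append((tid, name, str(exc)))
            return np.nan

    for target in targets:
        tid = target.target_id
        has_native = any(r.is_native for r in target.records)
        row = {"target_id": tid, "decoy_set": target.decoy_set or "all",
               "n_decoys": len(target.decoys)}
        if has_native:
            row["rank_native"] = attempt(tid, "rank", lambda: native_rank(target))
            row["zscore"] = attempt(tid, "zscore", lambda: zscore(target))
        else:
            row["rank_native"] = np.nan
            row["zscore"] = np.nan
        row["logPB1"] = attempt(tid, "logPB1", lambda: log_pb(target, 1))
        row["logPB10"] = attempt(
            tid, "logPB10",
            lambda: log_pb(target, min(10, len(target.decoys))))
        rt = attempt(tid, "correlation", lambda: correlations(target, False))
        row["pearson_r"], row["kendall_tau"] = (
            rt if isinstance(rt, tuple) else (np.nan, np.nan))
        if has_native:
            rtn = attempt(tid, "correlation_with_native",
                          lambda: correlations(target, True))
        else:
            rtn = (np.nan, np.nan)
        row["pearson_r_with_native"], row["kendall_tau_with_native"] = (
            rtn if isinstance(rtn, tuple) else (np.nan, np.nan))
        row["auc"] = attempt(
            tid, "auc", lambda: roc_auc(target, tm_threshold, min_positives))
        rows.append(row)

    per_target = pd.DataFrame(rows)
    summary_rows = []
    grouped = list(per_target.groupby("decoy_set")) if len(per_target) else []
    for name, group in grouped + ([("total", per_target)] if len(per_target) else []):
        summary_rows.append({
            "decoy_set": name,
            "targets": len(group),
            "rank1": int((group["rank_native"] == 1).sum()),
            "mean_zscore": group["zscore"].mean(),
            "mean_logPB1": group["logPB1"].mean(),
            "mean_logPB10": group["logPB10"].mean(),
            "mean_pearson_r": group["pearson_r"].mean(),
            "mean_kendall_tau": group["kendall_tau"].mean(),
            "mean_auc": group["auc"].mean(),
        })
    return {"per_target": per_target, "summary": pd.DataFrame(summary_rows),
            "skipped": skipped}


def read_manifest(path, sep: str | None = None) -> list[TargetSet]:
    """Read per-target decoy manifests from a TSV/CSV file.

    Columns: target_id, model_id, energy, quality, is_native and optionally
    decoy_set.  Quality may be empty for energy-only records.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    required = {"target_id", "model_id", "energy", "is_native"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    targets = []
    for tid, group in df.groupby("target_id", sort=False):
        records = [
            DecoyRecord(
                model_id=str(row.model_id),
                energy=float(row.energy),
                quality=(None if "quality" not in df.columns
                         or pd.isna(row.quality) else float(row.quality)),
                is_native=bool(row.is_native),
            )
            for row in group.itertuples()
        ]
        decoy_set = (str(group["decoy_set"].iloc[0])
                     if "decoy_set" in df.columns else "")
        targets.append(TargetSet(str(tid), records, decoy_set))
    return targets
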
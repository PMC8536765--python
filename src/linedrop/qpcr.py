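"""Delta-delta-Ct relative quantification and Mann-Whitney group comparison.

Relative transcript abundance is computed per sample as
2^-(ddCt) x 100%, where dCt = mean Ct(target) - mean Ct(reference) and
ddCt subtracts the median dCt of the calibrator group — so the
calibrator group's median is 100% by construction, matching the
"median% (IQR-IQR%)" reporting style.  Amplification efficiency is
fixed at 2.0 per cycle.

Group comparison uses the two-sided Mann-Whitney U test: exact by
enumeration for small samples (combined n <= 12, tie-safe), normal
approximation with tie and continuity corrections otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MAX_N = 12  # combined sample size at or below which the exact test runs


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate Ct values for one sample under one assay."""

    sample_id: str
    assay: str
    group: str
    cts: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.cts:
            raise ValueError(f"{self.sample_id}/{self.assay}: no replicates")
        if any(ct <= 0 for ct in self.cts):
            raise ValueError(f"{self.sample_id}/{self.assay}: Ct must be > 0")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.cts))


@dataclass
class RelativeExpression:
    """Per-sample relative quantities (% of calibrator-group median)."""

    per_sample: dict[str, float]
    groups: dict[str, list[str]]
    calibrator_group: str
    u: float
    p: float

    def quantities(self, group: str) -> np.ndarray:
        return np.array([self.per_sample[s] for s in self.groups[group]])

    def summary(self, group: str) -> tuple[float, float, float]:
        """(median, IQR low, IQR high) of a group's quantities, in %."""
        q = self.quantities(group)
        return (float(np.median(q)), float(np.percentile(q, 25)),
                float(np.percentile(q, 75)))

    def format_group(self, group: str) -> str:
        med, lo, hi = self.summary(group)
        return f"{med:.0f}% ({lo:.0f}-{hi:.0f}%)"

    def format_comparison(self) -> str:
        other = [g for g in self.groups if g != self.calibrator_group]
        left = " vs ".join(self.format_group(g) for g in other)
        return (f"{left} vs {self.format_group(self.calibrator_group)}, "
                f"p = {self.p:.2g}")


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   ) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Combined n <= 12: exact p from the full enumeration of rank
    assignments (handles ties), p = 2*min(P(U<=u), P(U>=u)) capped at 1.
    Larger samples: normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    nx, ny = x.size, y.size
    u_obs = sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0
                for xi in x for yi in y)
    if nx + ny <= EXACT_MAX_N:
        pooled = np.concatenate([x, y])
        n = pooled.size
        us = []
        for idx in combinations(range(n), nx):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            xs, ys = pooled[mask], pooled[~mask]
            us.append(sum(1.0 if a > b else 0.5 if a == b else 0.0
                          for a in xs for b in ys))
        us = np.array(us)
        p_le = float(np.mean(us <= u_obs))
        p_ge = float(np.mean(us >= u_obs))
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u_obs, p
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _group_by_sample(measurements: Sequence[QpcrMeasurement], assay: str,
                     ) -> dict[str, QpcrMeasurement]:
    return {m.sample_id: m for m in measurements if m.assay == assay}


def ddct_relative(measurements: Sequence[QpcrMeasurement], target_assay: str,
                  reference_assay: str, calibrator_group: str,
                  ) -> RelativeExpression:
    """Relative target expression, normalised within-sample to a reference
    assay and between-groups to the calibrator group's median dCt."""
    targets = _group_by_sample(measurements, target_assay)
    refs = _group_by_sample(measurements, reference_assay)
    samples = sorted(targets)
    missing = [s for s in samples if s not in refs] + \
              [s for s in refs if s not in targets]
    if missing:
        raise ValueError(f"samples missing one assay: {sorted(set(missing))}")
    groups: dict[str, list[str]] = {}
    dct: dict[str, float] = {}
    for s in samples:
        dct[s] = targets[s].mean_ct - refs[s].mean_ct
        groups.setdefault(targets[s].group, []).append(s)
    if calibrator_group not in groups:
        raise ValueError(f"no samples in calibrator group "
                         f"{calibrator_group!r}")
    cal_median = float(np.median([dct[s] for s in groups[calibrator_group]]))
    per_sample = {s: 100.0 * 2.0 ** -(dct[s] - cal_median) for s in samples}
    other = [g for g in groups if g != calibrator_group]
    if len(other) == 1:
        u, p = mann_whitney_u([per_sample[s] for s in groups[other[0]]],
                              [per_sample[s] for s in
                               groups[calibrator_group]])
    else:
        u, p = math.nan, math.nan
    return RelativeExpression(per_sample, groups, calibrator_group, u, p)


def allele_ratio(measurements: Sequence[QpcrMeasurement],
                 allele_i_assay: str, allele_m_assay: str,
                 calibrator_group: str) -> RelativeExpression:
    """Relative 148I:148M transcript ratio in I/M heterozygotes.

    The per-sample ratio 2^-(Ct_I - Ct_M) is the same construction as
    ddCt with the M-allele assay as the within-sample reference, so the
    result is normalised to the calibrator (non-insertion) group median.
    """
    return ddct_relative(measurements, target_assay=allele_i_assay,
                         reference_assay=allele_m_assay,
                         calibrator_group=calibrator_group)


def read_measurements(path: str | Path) -> list[QpcrMeasurement]:
    """Measurement TSV: sample_id, group, assay, then one column per
    replicate Ct (ct1, ct2, ct3, ...)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    ct_cols = [c for c in df.columns if c.startswith("ct")]
    out = []
    for _, row in df.iterrows():
        cts = tuple(float(row[c]) for c in ct_cols if pd.notna(row[c]))
        out.append(QpcrMeasurement(str(row["sample_id"]), str(row["assay"]),
                                   str(row["group"]), cts))
    return out


def write_measurements(measurements: Sequence[QpcrMeasurement],
                       path: str | Path) -> None:
    n_rep = max(len(m.cts) for m in measurements)
    cols = [f"ct{i + 1}" for i in range(n_rep)]
    rows = []
    for m in measurements:
        row = {"sample_id": m.sample_id, "group": m.group, "assay": m.assay}
        row.update({c: (m.cts[i] if i < len(m.cts) else None)
                    for i, c in enumerate(cols)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
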
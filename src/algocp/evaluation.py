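"""Set-level evaluation of generated sequences against the input MSA.

The core diagnostic: per retained position, the mean (H_KD, pI, vdW) of a
sequence set is compared to the same positional means of the MSA by squared
Pearson correlation. Sweeping the mixing coefficient r and averaging the
three per-property R² values per set gives one curve; the residual of each
set's average R² against the grand mean across the sweep localises the
balance point between conservation-faithful (negative residual side) and
physicochemically explorative (positive side) designs — the selected r is
the one closest to the grand mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import AA_INDEX
from .msa import AlignmentColumn
from .profiles import PositionProfile
from .generator import GeneratedSet, sample_unique
from .profiles import reweight_profiles
from .properties import PropertyTable, default_property_table, gravy, sequence_pi

PROPERTIES = ("h_kd", "pi", "vdw")


def positional_property_means(
    seqs_or_columns: Sequence[str] | Sequence[AlignmentColumn],
    table: PropertyTable | None = None,
) -> pd.DataFrame:
    """Mean (H_KD, pI, vdW) per position.

    Accepts either a set of equal-length ungapped sequences or MSA columns
    (gaps/ambiguities already excluded from column multisets). Returns a
    DataFrame indexed by 0-based position with columns h_kd/pi/vdw.
    """
    table = table or default_property_table()
    items = list(seqs_or_columns)
    if not items:
        raise ValueError("empty input")
    if isinstance(items[0], AlignmentColumn):
        rows = []
        for col in items:
            total = np.zeros(3)
            for aa, count in col.residues.items():
                total += count * table.matrix[AA_INDEX[aa]]
            rows.append(total / col.depth)
        return pd.DataFrame(rows, columns=list(PROPERTIES))
    length = len(items[0])
    if any(len(s) != length for s in items):
        raise ValueError("sequences must share one length")
    idx = np.array([[AA_INDEX[ch] for ch in s] for s in items])  # (n, L)
    means = table.matrix[idx].mean(axis=0)  # (L, 3)
    return pd.DataFrame(means, columns=list(PROPERTIES))


def pairwise_property_correlation(
    set_profile: pd.DataFrame, msa_profile: pd.DataFrame
) -> tuple[float, float, float]:
    """Squared Pearson correlation across positions, one value per property."""
    if len(set_profile) != len(msa_profile):
        raise ValueError("profiles must cover the same number of positions")
    out = []
    for prop in PROPERTIES:
        x = set_profile[prop].to_numpy()
        y = msa_profile[prop].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"undefined correlation: constant {prop} profile")
        r, _ = stats.pearsonr(x, y)
        out.append(float(r * r))
    return tuple(out)


@dataclass(frozen=True)
class CorrelationReport:
    """Per-sweep-point record: R² per property and their average."""

    r: float
    r2_hkd: float
    r2_pi: float
    r2_vdw: float

    @property
    def avg_r2(self) -> float:
        return (self.r2_hkd + self.r2_pi + self.r2_vdw) / 3.0


def residual_balance_analysis(
    reports: Sequence[CorrelationReport],
) -> tuple[pd.DataFrame, float]:
    """Signed residuals of per-set average R² against the sweep grand mean.

    Returns ``(table, selected_r)`` where the table has one row per sweep
    point (r, r2 per property, avg_r2, residual, selected flag) and
    ``selected_r`` minimises |residual| (ties to the smaller r).
    """
    if not reports:
        raise ValueError("empty sweep")
    if len(reports) < 2:
        raise ValueError("residual analysis needs at least 2 sweep points")
    avg = np.array([rep.avg_r2 for rep in reports])
    grand_mean = float(avg.mean())
    residuals = avg - grand_mean
    order = np.lexsort((np.array([rep.r for rep in reports]), np.abs(residuals)))
    selected_idx = int(order[0])
    df = pd.DataFrame(
        {
            "r": [rep.r for rep in reports],
            "r2_hkd": [rep.r2_hkd for rep in reports],
            "r2_pi": [rep.r2_pi for rep in reports],
            "r2_vdw": [rep.r2_vdw for rep in reports],
            "avg_r2": avg,
            "residual": residuals,
        }
    )
    df["selected"] = False
    df.loc[selected_idx, "selected"] = True
    df.attrs["grand_mean"] = grand_mean
    return df, float(df.loc[selected_idx, "r"])


def default_r_grid(step: float = 0.05) -> np.ndarray:
    """Inclusive 0..1 grid (21 points at the default step)."""
    n = int(round(1.0 / step))
    return np.round(np.linspace(0.0, 1.0, n + 1), 10)


def r_sweep(
    profiles: Sequence[PositionProfile],
    msa_columns: Sequence[AlignmentColumn],
    n_per_set: int = 5000,
    seed: int = 0,
    r_values: Sequence[float] | None = None,
    table: PropertyTable | None = None,
    max_attempts_factor: int = 20,
) -> list[CorrelationReport]:
    """Generate one sequence set per r and correlate each against the MSA.

    Each sweep point uses an independent RNG substream derived from
    ``(seed, point index)`` so sets are uncorrelated across the sweep.
    """
    table = table or default_property_table()
    r_values = default_r_grid() if r_values is None else list(r_values)
    msa_profile = positional_property_means(msa_columns, table)
    reports = []
    for k, r in enumerate(r_values):
        sub_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
        seqs = sample_unique(
            reweight_profiles(profiles, r), n_per_set, sub_seed, max_attempts_factor
        )
        set_profile = positional_property_means(seqs, table)
        r2 = pairwise_property_correlation(set_profile, msa_profile)
        reports.append(CorrelationReport(float(r), *r2))
    return reports


def sequence_set_summary(
    seqs: Sequence[str] | GeneratedSet,
    table: PropertyTable | None = None,
    pka_set: str = "emboss",
) -> pd.DataFrame:
    """Per-sequence GRAVY and pI, with set mean and normal 95% CI in attrs.

    CI half-width is 1.96·sd/√n; reported as NaN for a single sequence.
    """
    table = table or default_property_table()
    seqs = list(seqs)
    if not seqs:
        raise ValueError("empty sequence set")
    df = pd.DataFrame(
        {
            "sequence": seqs,
            "gravy": [gravy(s, table) for s in seqs],
            "pi": [sequence_pi(s, pka_set) for s in seqs],
        }
    )
    n = len(df)
    for col in ("gravy", "pi"):
        df.attrs[f"mean_{col}"] = float(df[col].mean())
        if n > 1:
            half = 1.96 * float(df[col].std(ddof=1)) / np.sqrt(n)
        else:
            half = float("nan")
        df.attrs[f"ci95_{col}"] = half
    return df
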
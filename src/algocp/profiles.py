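"""Position-specific probability profiles over the 20 amino acids.

Each retained alignment column yields three distributions:

* the conservation route ``A_C``: observed residue frequencies ``f/N``,
  with a modal override — a column whose most frequent residue reaches the
  conservation cutoff (default 90% identity) collapses to probability 1 on
  that residue, so functionally essential positions (e.g. the modifiable
  serine of a carrier protein) are preserved verbatim;
* the physicochemical route ``A_P``: every canonical residue ``a`` is
  scored against the column's mean property vector ``x̄`` by a weighted sum
  of reciprocal absolute differences,

      S(a) = Σ_k  w_k / (|x_{a,k} − x̄_k| + ε),   k ∈ {H_KD, pI, vdW}

  normalised to a distribution. Its support is all 20 residues, which is
  what lets the sampler propose substitutions never observed in the MSA;
* the unified profile ``A_U = r·A_P + (1−r)·A_C`` for a mixing coefficient
  ``r`` in [0, 1]. The modal override wins at every r, including r = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, AA_INDEX, N_AA
from .msa import AlignmentColumn
from .properties import PropertyTable, PropertyVector, default_property_table

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the profile computation.

    Weights follow the study defaults (H_KD 0.22, pI 0.44, vdW 0.33) and
    are renormalised internally to sum to 1, preserving their ratios.
    ``standardize`` optionally z-scores the three property axes across the
    20 residues before the reciprocal-difference scoring (off by default:
    the unequal weights already compensate for scale differences).
    """

    w_hkd: float = 0.22
    w_pi: float = 0.44
    w_vdw: float = 0.33
    epsilon: float = 1e-6
    conservation_cutoff: float = 0.90
    r: float = 0.60
    standardize: bool = False

    def __post_init__(self) -> None:
        w = np.array([self.w_hkd, self.w_pi, self.w_vdw], dtype=float)
        if np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative and not all zero")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0 < self.conservation_cutoff <= 1:
            raise ValueError("conservation_cutoff must lie in (0, 1]")
        if not 0 <= self.r <= 1:
            raise ValueError("r must lie in [0, 1]")

    @property
    def weights(self) -> np.ndarray:
        """Normalised (sum-1) property weights."""
        w = np.array([self.w_hkd, self.w_pi, self.w_vdw], dtype=float)
        return w / w.sum()


@dataclass(frozen=True)
class PositionProfile:
    """The three distributions at one retained column.

    ``column_index`` is the 0-based position in the *original* alignment.
    When ``conserved_override`` is set, all three vectors place probability
    1 on ``modal_residue``.
    """

    column_index: int
    a_c: np.ndarray
    a_p: np.ndarray
    a_u: np.ndarray
    conserved_override: bool
    modal_residue: str | None
    depth: int = 0

    def __post_init__(self) -> None:
        for name in ("a_c", "a_p", "a_u"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (N_AA,):
                raise ValueError(f"{name} must have shape (20,)")
            if v.min() < 0 or abs(v.sum() - 1.0) > _SUM_TOL:
                raise ValueError(f"{name} is not a probability distribution")
            object.__setattr__(self, name, v)
        if self.conserved_override:
            if self.modal_residue is None:
                raise ValueError("override profile needs a modal residue")
            if self.a_u[AA_INDEX[self.modal_residue]] != 1.0:
                raise ValueError("override profile must collapse a_u onto the modal residue")


def conservation_distribution(
    col: AlignmentColumn, cutoff: float = 0.90
) -> tuple[np.ndarray, bool, str]:
    """Frequency distribution f/N for one column, with the modal override.

    Returns ``(distribution, override, modal_residue)``. Ties at the modal
    position break alphabetically (deterministic). When the modal frequency
    reaches ``cutoff`` the distribution collapses to the modal residue.
    """
    n = col.depth
    if n == 0:
        raise ValueError(f"column {col.index}: empty (no canonical residues)")
    dist = np.zeros(N_AA)
    for aa, count in col.residues.items():
        dist[AA_INDEX[aa]] = count / n
    modal_idx = int(np.argmax(dist))  # argmax takes the first = alphabetical tie-break
    modal = AMINO_ACIDS[modal_idx]
    if dist[modal_idx] >= cutoff:
        collapsed = np.zeros(N_AA)
        collapsed[modal_idx] = 1.0
        return collapsed, True, modal
    return dist, False, modal


def column_property_mean(
    col: AlignmentColumn, table: PropertyTable | None = None
) -> PropertyVector:
    """Mean (H_KD, pI, vdW) over the column multiset, duplicates counted."""
    table = table or default_property_table()
    if col.depth == 0:
        raise ValueError(f"column {col.index}: empty (no canonical residues)")
    total = np.zeros(3)
    for aa, count in col.residues.items():
        total += count * table.matrix[AA_INDEX[aa]]
    return PropertyVector(*(total / col.depth))


def physchem_distribution(
    mean: PropertyVector,
    table: PropertyTable | None = None,
    cfg: ScoringConfig | None = None,
) -> np.ndarray:
    """Weighted reciprocal-difference similarity, normalised over all 20.

    Every residue receives strictly positive probability, so this route can
    propose substitutions absent from the input alignment.
    """
    table = table or default_property_table()
    cfg = cfg or ScoringConfig()
    props = table.matrix
    target = np.asarray(mean, dtype=float)
    if cfg.standardize:
        mu, sd = props.mean(axis=0), props.std(axis=0)
        props = (props - mu) / sd
        target = (target - mu) / sd
    diffs = np.abs(props - target)  # (20, 3)
    scores = (cfg.weights / (diffs + cfg.epsilon)).sum(axis=1)
    return scores / scores.sum()


def unified_profile(
    a_c: np.ndarray,
    a_p: np.ndarray,
    override: bool,
    modal: str | None,
    r: float,
) -> np.ndarray:
    """A_U = r·A_P + (1−r)·A_C; the modal override collapses A_U at any r."""
    if not 0 <= r <= 1:
        raise ValueError("r must lie in [0, 1]")
    if override:
        if modal is None:
            raise ValueError("override requires a modal residue")
        out = np.zeros(N_AA)
        out[AA_INDEX[modal]] = 1.0
        return out
    return r * a_p + (1.0 - r) * a_c


def build_profiles(
    columns: Sequence[AlignmentColumn],
    table: PropertyTable | None = None,
    cfg: ScoringConfig | None = None,
) -> list[PositionProfile]:
    """Compute the full per-column profile list for a columnarised MSA."""
    table = table or default_property_table()
    cfg = cfg or ScoringConfig()
    profiles = []
    for col in columns:
        a_c, override, modal = conservation_distribution(col, cfg.conservation_cutoff)
        a_p = physchem_distribution(column_property_mean(col, table), table, cfg)
        a_u = unified_profile(a_c, a_p, override, modal, cfg.r)
        profiles.append(
            PositionProfile(
                column_index=col.index,
                a_c=a_c,
                a_p=a_p,
                a_u=a_u,
                conserved_override=override,
                modal_residue=modal,
                depth=col.depth,
            )
        )
    return profiles


def reweight_profiles(profiles: Sequence[PositionProfile], r: float) -> list[PositionProfile]:
    """Recombine stored A_C/A_P at a new r without touching the alignment."""
    out = []
    for p in profiles:
        a_u = unified_profile(p.a_c, p.a_p, p.conserved_override, p.modal_residue, r)
        out.append(replace(p, a_u=a_u))
    return out


def profiles_to_frame(profiles: Sequence[PositionProfile]) -> pd.DataFrame:
    """Flat table of all profiles: one row per retained column, 1-based
    positions, 20 columns per distribution."""
    rows = []
    for p in profiles:
        row = {
            "position": p.column_index + 1,
            "depth": p.depth,
            "override": p.conserved_override,
            "modal": p.modal_residue,
        }
        for tag, vec in (("c", p.a_c), ("p", p.a_p), ("u", p.a_u)):
            for aa, v in zip(AMINO_ACIDS, vec):
                row[f"a{tag}_{aa}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
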
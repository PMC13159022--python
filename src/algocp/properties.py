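"""Per-residue physicochemical tables and sequence-level descriptors.

Two distinct uses of isoelectric point live here on purpose: the *residue*
pI column of :class:`PropertyTable` feeds the physicochemical scoring route,
while :func:`sequence_pi` models a whole chain's titration
(Henderson-Hasselbalch net charge, solved by bisection) for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, AA_INDEX, N_AA, validate_sequence


class PropertyVector(NamedTuple):
    """A point in (hydropathy, residue pI, van der Waals volume) space."""

    h_kd: float
    pi: float
    vdw: float


PROPERTY_NAMES = ("h_kd", "pi", "vdw")


@dataclass(frozen=True)
class PropertyTable:
    """Physicochemical values for the 20 canonical amino acids.

    ``matrix`` is a (20, 3) array ordered by :data:`~algocp.alphabet.AMINO_ACIDS`
    rows and ``(h_kd, pi, vdw)`` columns. ``source`` is a provenance tag.
    """

    matrix: np.ndarray
    source: str = "builtin"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_AA, 3):
            raise ValueError(f"property matrix must be (20, 3), got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("property matrix contains non-finite values")
        h, pi, vdw = m[:, 0], m[:, 1], m[:, 2]
        if h.min() < -5 or h.max() > 5:
            raise ValueError("hydropathy values outside [-5, 5]")
        if pi.min() < 2 or pi.max() > 12:
            raise ValueError("residue pI values outside [2, 12]")
        if vdw.min() < 40 or vdw.max() > 250:
            raise ValueError("vdW volumes outside [40, 250] A^3")
        object.__setattr__(self, "matrix", m)

    def vector(self, residue: str) -> PropertyVector:
        """Property vector for one canonical residue.

        Ambiguity codes carry no property data and raise ValueError.
        """
        try:
            row = self.matrix[AA_INDEX[residue]]
        except KeyError:
            raise ValueError(f"no property data for residue {residue!r}") from None
        return PropertyVector(*row)

    @property
    def h_kd(self) -> np.ndarray:
        return self.matrix[:, 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(AMINO_ACIDS), columns=PROPERTY_NAMES)

    @classmethod
    def from_tsv(cls, path, source: str | None = None) -> "PropertyTable":
        df = pd.read_csv(path, sep="\t", comment="#").set_index("aa")
        missing = set(AMINO_ACIDS) - set(df.index)
        if missing:
            raise ValueError(f"property table missing residues: {sorted(missing)}")
        m = df.loc[list(AMINO_ACIDS), list(PROPERTY_NAMES)].to_numpy(dtype=float)
        return cls(m, source=source or str(path))


_DEFAULT_TABLE: PropertyTable | None = None


def default_property_table() -> PropertyTable:
    """The shipped table: Kyte-Doolittle H_KD, Zimmerman residue pI,
    Darby-Creighton vdW volume (A^3)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        with resources.files("algocp.data").joinpath("aa_properties.tsv").open() as fh:
            _DEFAULT_TABLE = PropertyTable.from_tsv(fh, source="algocp builtin (KD/Zimmerman/Darby-Creighton)")
    return _DEFAULT_TABLE


def residue_properties(residue: str, table: PropertyTable | None = None) -> PropertyVector:
    table = table or default_property_table()
    return table.vector(residue)


def gravy(seq: str, table: PropertyTable | None = None) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value over the chain."""
    table = table or default_property_table()
    seq = validate_sequence(seq, context="gravy")
    return float(np.mean([table.matrix[AA_INDEX[ch], 0] for ch in seq]))


# ---------------------------------------------------------------------------
# Sequence isoelectric point

# pKa parameterisations: (n_term, c_term, side-chain pKa per ionisable residue).
# Positive groups: N-terminus, H, K, R. Negative: C-terminus, D, E, C, Y.
PKA_SETS: dict[str, dict[str, float]] = {
    # EMBOSS iep defaults
    "emboss": {
        "n_term": 8.6, "c_term": 3.6,
        "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
    },
    # Bjellqvist et al. 1993 (as used by ExPASy compute pI)
    "bjellqvist": {
        "n_term": 7.5, "c_term": 3.55,
        "C": 9.0, "D": 4.05, "E": 4.45, "H": 5.98, "K": 10.0, "R": 12.0, "Y": 10.0,
    },
}

_POSITIVE = ("H", "K", "R")
_NEGATIVE = ("D", "E", "C", "Y")


def net_charge(seq: str, ph: float | np.ndarray, pka_set: str = "emboss"):
    """Modelled net charge of a peptide at the given pH (scalar or array).

    Henderson-Hasselbalch per ionisable group; termini always counted.
    """
    pka = PKA_SETS[pka_set]
    seq = validate_sequence(seq, context="net_charge")
    ph = np.asarray(ph, dtype=float)
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka["n_term"]))
    charge = charge - 1.0 / (1.0 + 10.0 ** (pka["c_term"] - ph))
    for res in _POSITIVE:
        n = seq.count(res)
        if n:
            charge = charge + n / (1.0 + 10.0 ** (ph - pka[res]))
    for res in _NEGATIVE:
        n = seq.count(res)
        if n:
            charge = charge - n / (1.0 + 10.0 ** (pka[res] - ph))
    return charge if charge.shape else float(charge)


def sequence_pi(seq: str, pka_set: str = "emboss", tol: float = 1e-4) -> float:
    """Isoelectric point: the pH in [0, 14] where modelled net charge is zero.

    The net-charge function is strictly decreasing in pH, so bisection
    converges unconditionally; result within ``tol`` pH units.
    """
    if pka_set not in PKA_SETS:
        raise ValueError(f"unknown pKa set {pka_set!r}; options: {sorted(PKA_SETS)}")
    seq = validate_sequence(seq, context="sequence_pi")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
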
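"""Intact-mass arithmetic for carrier-protein PTM states.

A carrier protein is produced *apo*; a phosphopantetheinyl transferase
attaches the 4'-phosphopantetheine arm of coenzyme A to the invariant
serine (apo → holo, net adduct C11H21N2O6PS, ≈ +340.3 Da average), and an
acyl-ACP synthetase thioesterifies a fatty acid onto the arm's terminal
thiol (holo → acyl-Cn, net adduct CnH(2n−2)O; +182.3 Da for laurate/C12).
Deconvoluted ESI-MS masses are assigned to the nearest expected state.

Average masses are the default, matching deconvoluted intact-protein
practice; monoisotopic mode is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import molecular_weight
from pyteomics import mass as _pmass

from .alphabet import validate_sequence

#: Net mass addition of 4'-phosphopantetheinylation (phosphopantetheine
#: condensed onto serine with loss of water).
HOLO_ADDUCT_FORMULA = "C11H21N2O6PS"


def formula_mass(formula: str, monoisotopic: bool = False) -> float:
    """Mass of a chemical formula in Da (average by default)."""
    return float(_pmass.calculate_mass(formula=formula, average=not monoisotopic))


def delta_holo(monoisotopic: bool = False) -> float:
    """apo → holo mass shift (≈ 340.33 Da average)."""
    return formula_mass(HOLO_ADDUCT_FORMULA, monoisotopic)


def acyl_formula(n_carbons: int) -> str:
    """Net adduct of a saturated n-carbon acyl thioester: the fatty acid
    minus water, CnH(2n−2)O."""
    if n_carbons < 2:
        raise ValueError("acyl chains need at least 2 carbons")
    return f"C{n_carbons}H{2 * n_carbons - 2}O"


def delta_acyl(n_carbons: int, monoisotopic: bool = False) -> float:
    """holo → acyl-Cn mass shift (≈ 182.30 Da average for C12)."""
    return formula_mass(acyl_formula(n_carbons), monoisotopic)


def average_mass(seq: str, monoisotopic: bool = False) -> float:
    """Intact chain mass: residue masses plus one water, in Da."""
    seq = validate_sequence(seq, context="average_mass")
    return float(molecular_weight(seq, seq_type="protein", monoisotopic=monoisotopic))


def ptm_state_masses(
    seq: str, acyl_carbons: list[int] | None = None, monoisotopic: bool = False
) -> dict[str, float]:
    """Expected intact masses per PTM state.

    Returns ``{"apo": ..., "holo": ..., "acyl-Cn": ...}``; masses increase
    strictly along apo < holo < acyl-Cn.
    """
    acyl_carbons = [12] if acyl_carbons is None else list(acyl_carbons)
    apo = average_mass(seq, monoisotopic)
    holo = apo + delta_holo(monoisotopic)
    out = {"apo": apo, "holo": holo}
    for n in sorted(acyl_carbons):
        out[f"acyl-C{n}"] = holo + delta_acyl(n, monoisotopic)
    return out


#: Modification order used for tie-breaking: less-modified states first.
_STATE_ORDER = {"apo": 0, "holo": 1}


def _state_rank(state: str) -> tuple[int, int]:
    if state in _STATE_ORDER:
        return (_STATE_ORDER[state], 0)
    if state.startswith("acyl-C"):
        return (2, int(state[6:]))
    return (3, 0)


@dataclass(frozen=True)
class StateAssignment:
    """Nearest-state call for one observed deconvoluted mass."""

    observed_mass: float
    best_state: str  # "unassigned" when nothing falls within tolerance
    error: float  # observed − expected, Da (nan when unassigned)
    tolerance: float


def assign_ptm_state(
    observed: float, expected: dict[str, float], tolerance: float = 1.0
) -> StateAssignment:
    """Assign an observed mass to the expected state minimising |error|.

    Ties break toward the less-modified state; above tolerance the mass is
    left unassigned.
    """
    if not expected:
        raise ValueError("empty expected-state map")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    best = min(expected.items(), key=lambda kv: (abs(observed - kv[1]), _state_rank(kv[0])))
    state, exp_mass = best
    err = observed - exp_mass
    if abs(err) > tolerance:
        return StateAssignment(observed, "unassigned", float("nan"), tolerance)
    return StateAssignment(observed, state, err, tolerance)
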
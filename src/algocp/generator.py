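"""Stochastic sequence sampling from positional profiles.

:class:`ProfileSequenceGenerator` is the user-facing estimator: ``fit`` on
an alignment (or pre-extracted columns) computes the positional profiles,
``sample`` draws sets of unique sequences from them. Chimera generation of
two pre-aligned parents reuses the conservation route on a two-row
alignment: identical columns are inherited verbatim, differing columns are
a fair coin between the parents.

Reproducibility contract: sequence *i* of a run is drawn from an RNG
substream keyed by ``(seed, i)``, so it does not depend on how many other
sequences are requested. Within a sequence, draws run left to right.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .alphabet import AMINO_ACIDS, decode, validate_sequence, GAP
from .msa import Alignment, AlignmentColumn, SequenceRecord, extract_columns
from .profiles import PositionProfile, ScoringConfig, build_profiles, reweight_profiles
from .properties import PropertyTable, default_property_table


@dataclass(frozen=True)
class GenerationConfig:
    """Sampling parameters: set size, mixing coefficient, seed, and the
    duplicate-rejection budget (attempts allowed = factor x n_sequences)."""

    n_sequences: int = 5000
    r: float = 0.60
    seed: int = 0
    max_attempts_factor: int = 20
    scoring: ScoringConfig = field(default_factory=ScoringConfig)

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if self.max_attempts_factor < 2:
            raise ValueError("max_attempts_factor must be >= 2")
        if not 0 <= self.r <= 1:
            raise ValueError("r must lie in [0, 1]")


@dataclass(frozen=True)
class GeneratedSet:
    """A set of pairwise-distinct, equal-length ungapped sequences plus the
    provenance needed to regenerate it."""

    sequences: tuple[str, ...]
    provenance: dict

    def __post_init__(self) -> None:
        seqs = tuple(self.sequences)
        if not seqs:
            raise ValueError("empty generated set")
        length = len(seqs[0])
        if any(len(s) != length for s in seqs):
            raise ValueError("generated sequences must share one length")
        if len(set(seqs)) != len(seqs):
            raise ValueError("generated sequences must be pairwise distinct")
        object.__setattr__(self, "sequences", seqs)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)


def _profile_matrix(profiles: Sequence[PositionProfile]) -> np.ndarray:
    return np.stack([p.a_u for p in profiles])  # (L, 20)


def _draw_sequence(cum: np.ndarray, seed: int, index: int) -> str:
    """Draw one sequence from cumulative positional distributions; the
    substream is keyed by (seed, index)."""
    rng = np.random.default_rng([seed, index])
    u = rng.random(cum.shape[0])
    idx = (u[:, None] >= cum[:, :-1]).sum(axis=1)
    return decode(idx)


def sample_unique(
    profiles: Sequence[PositionProfile],
    n_sequences: int,
    seed: int,
    max_attempts_factor: int = 20,
) -> list[str]:
    """Rejection-sample ``n_sequences`` distinct sequences from A_U.

    Raises if the attempt budget is exhausted (e.g. a fully conserved
    profile admits only one outcome), reporting the diversity achieved.
    """
    if not profiles:
        raise ValueError("no profiles to sample from")
    probs = _profile_matrix(profiles)
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0  # guard against float drift at the top bin
    unique: list[str] = []
    seen: set[str] = set()
    budget = max_attempts_factor * n_sequences
    for attempt in range(budget):
        seq = _draw_sequence(cum, seed, attempt)
        if seq not in seen:
            seen.add(seq)
            unique.append(seq)
            if len(unique) == n_sequences:
                return unique
    raise RuntimeError(
        f"could only draw {len(unique)} unique sequences in {budget} attempts "
        f"(requested {n_sequences}); the profile may be too conserved"
    )


class ProfileSequenceGenerator(BaseEstimator):
    """Generative model over protein sequences, fit on an MSA.

    Parameters mirror :class:`~algocp.profiles.ScoringConfig`: ``r`` mixes
    the physicochemical route (r=1) against the conservation route (r=0);
    ``weights`` order is (H_KD, pI, vdW); columns shallower than
    ``min_residues`` are dropped before profiling.

    Fitted attributes: ``profiles_`` (list of PositionProfile),
    ``n_positions_``, ``alignment_digest_``.
    """

    def __init__(
        self,
        r: float = 0.60,
        weights: tuple[float, float, float] = (0.22, 0.44, 0.33),
        epsilon: float = 1e-6,
        conservation_cutoff: float = 0.90,
        min_residues: int = 50,
        standardize: bool = False,
        property_table: PropertyTable | None = None,
    ):
        self.r = r
        self.weights = weights
        self.epsilon = epsilon
        self.conservation_cutoff = conservation_cutoff
        self.min_residues = min_residues
        self.standardize = standardize
        self.property_table = property_table

    def _scoring_config(self) -> ScoringConfig:
        w = self.weights
        return ScoringConfig(
            w_hkd=w[0], w_pi=w[1], w_vdw=w[2],
            epsilon=self.epsilon,
            conservation_cutoff=self.conservation_cutoff,
            r=self.r,
            standardize=self.standardize,
        )

    def fit(self, X: Alignment | Sequence[AlignmentColumn], y=None):
        """Compute positional profiles from an Alignment or column list."""
        if isinstance(X, Alignment):
            columns = extract_columns(X, min_residues=self.min_residues)
            digest = hashlib.sha256(
                "".join(rec.residues for rec in X.records).encode()
            ).hexdigest()[:16]
        else:
            columns = list(X)
            digest = hashlib.sha256(
                str([(c.index, sorted(c.residues.items())) for c in columns]).encode()
            ).hexdigest()[:16]
        table = self.property_table or default_property_table()
        self.profiles_ = build_profiles(columns, table, self._scoring_config())
        self.n_positions_ = len(self.profiles_)
        self.alignment_digest_ = digest
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "profiles_"):
            raise RuntimeError("generator is not fitted; call fit() first")

    def profiles_at(self, r: float) -> list[PositionProfile]:
        """The fitted profiles recombined at a different r (cheap: A_C and
        A_P are cached per column)."""
        self._check_fitted()
        return reweight_profiles(self.profiles_, r)

    def sample(
        self,
        n_sequences: int = 1,
        seed: int = 0,
        r: float | None = None,
        max_attempts_factor: int = 20,
    ) -> GeneratedSet:
        """Draw a set of unique sequences from the positional A_U."""
        self._check_fitted()
        r_eff = self.r if r is None else r
        profiles = self.profiles_ if r is None else self.profiles_at(r)
        seqs = sample_unique(profiles, n_sequences, seed, max_attempts_factor)
        cfg = self._scoring_config()
        return GeneratedSet(
            sequences=tuple(seqs),
            provenance={
                "r": r_eff,
                "seed": seed,
                "weights": list(cfg.weights),
                "conservation_cutoff": cfg.conservation_cutoff,
                "epsilon": cfg.epsilon,
                "min_residues": self.min_residues,
                "alignment_digest": self.alignment_digest_,
            },
        )


def generate_sequences(
    profiles: Sequence[PositionProfile], cfg: GenerationConfig
) -> GeneratedSet:
    """Functional entry point: sample a unique set from given profiles."""
    profiles = reweight_profiles(profiles, cfg.r)
    seqs = sample_unique(profiles, cfg.n_sequences, cfg.seed, cfg.max_attempts_factor)
    return GeneratedSet(
        sequences=tuple(seqs),
        provenance={
            "r": cfg.r,
            "seed": cfg.seed,
            "weights": list(cfg.scoring.weights),
            "conservation_cutoff": cfg.scoring.conservation_cutoff,
            "epsilon": cfg.scoring.epsilon,
        },
    )


def generate_chimeras(
    parent_a: str, parent_b: str, n: int, seed: int
) -> GeneratedSet:
    """Recombine two equal-length, pre-aligned parents position by position.

    Identical columns are inherited with probability 1; differing columns
    are a 0.5/0.5 choice between the parental residues (the conservation
    route on a two-row alignment). Every output position therefore equals
    one of the two parental residues.
    """
    if GAP in parent_a or GAP in parent_b:
        raise ValueError("gapped parent columns are not supported; supply ungapped, "
                         "equal-length parents")
    parent_a = validate_sequence(parent_a, context="parent_a")
    parent_b = validate_sequence(parent_b, context="parent_b")
    if len(parent_a) != len(parent_b):
        raise ValueError("parents must have equal length (pre-aligned)")
    if n < 1:
        raise ValueError("n must be >= 1")
    diff_positions = [i for i, (a, b) in enumerate(zip(parent_a, parent_b)) if a != b]
    d = len(diff_positions)
    if d == 0 and n > 1:
        raise ValueError("identical parents admit a single chimera; requested n > 1")
    if d < 64 and n > 2 ** d:
        raise ValueError(
            f"parents differ at {d} positions: only 2^{d} = {2 ** d} distinct "
            f"chimeras exist, requested {n}"
        )
    columns = [
        AlignmentColumn(index=i, residues=Counter((parent_a[i], parent_b[i])))
        for i in range(len(parent_a))
    ]
    # route-A_C at r=0: identical columns collapse via the override, differing
    # columns sit at 0.5/0.5 (below any sensible cutoff).
    profiles = build_profiles(columns, cfg=ScoringConfig(r=0.0))
    seqs = sample_unique(profiles, n, seed, max_attempts_factor=max(4, 4 * (n.bit_length())))
    return GeneratedSet(
        sequences=tuple(seqs),
        provenance={
            "mode": "chimera",
            "seed": seed,
            "n_differing_positions": d,
            "parent_a_digest": hashlib.sha256(parent_a.encode()).hexdigest()[:16],
            "parent_b_digest": hashlib.sha256(parent_b.encode()).hexdigest()[:16],
        },
    )
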
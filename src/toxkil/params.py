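"""Model parameters in lumped and raw form.

The simulator's behaviour is governed by six *lumped* parameters (the
dimensionless/scale-combined quantities that fully determine the dynamics)
plus a block of fixed mutation and timing constants.  The lumped set is:

``L_cue``
    characteristic length scale of the density-cue concentration profile,
    ``sqrt(2 * D_cue / d_cue)``, in lattice sites.
``L_tox``
    characteristic length scale of the toxin profile, in lattice sites.
``R0_inv``
    ``delta / gamma``: the inverse of the maximal expected number of
    offspring per cell lifetime.  A cost-free population equilibrates at
    occupied fraction ``1 - R0_inv``.
``bT_hat``
    scaled slope of the toxin production cost function,
    ``gamma * d_tox * b_T / delta_tox``.
``C_R`` / ``C_C``
    costs of resistance and of cue responsiveness, as fractions of the
    maximal reproduction rate.

Expanding the lumped set into raw rates requires a unit convention (how
long a time step is, how concentrations are normalised).  The default
:class:`UnitConventions` fixes degradation rates at 1 per step, the cue
production rate so a fully occupied lattice yields cue concentration 1,
the per-cell toxin production at ``pi_T * d_tox`` so a fully producing
lattice yields toxin concentration ``pi_T``, and ``delta_tox = gamma``.
Under that convention ``b_T == bT_hat`` and model behaviour depends on
the lumped parameters only.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, fields, replace

import numpy as np

__all__ = [
    "LumpedParams",
    "RawParams",
    "UnitConventions",
    "SWEEP_RANGES",
    "expand_lumped",
    "lump",
    "sample_sweep",
    "carrying_capacity",
]

#: Default per-step reproduction-rate scale.  With gamma = ln(2)/10 the
#: minimal doubling time of a cost-free cell is ~10 time steps.
DEFAULT_GAMMA = math.log(2.0) / 10.0

#: Parameter-sweep sampling intervals for the six lumped parameters.
SWEEP_RANGES: dict[str, tuple[float, float]] = {
    "L_cue": (2.0, 20.0),
    "L_tox": (2.0, 38.0),
    "R0_inv": (0.0, 0.5),
    "bT_hat": (0.01, 0.8),
    "C_R": (0.01, 0.25),
    "C_C": (0.01, 0.1),
}


class ParamError(ValueError):
    """A parameter value is outside its valid range."""


class NonviablePopulationError(ParamError):
    """R0 <= 1: every lineage is expected to die out."""


@dataclass(frozen=True)
class LumpedParams:
    """The six behaviour-defining lumped parameters."""

    L_cue: float
    L_tox: float
    R0_inv: float
    bT_hat: float
    C_R: float
    C_C: float

    def __post_init__(self) -> None:
        if not self.L_cue > 0:
            raise ParamError(f"L_cue must be > 0, got {self.L_cue}")
        if not self.L_tox > 0:
            raise ParamError(f"L_tox must be > 0, got {self.L_tox}")
        if not 0.0 <= self.R0_inv < 1.0:
            raise ParamError(f"R0_inv must be in [0, 1), got {self.R0_inv}")
        if self.bT_hat < 0:
            raise ParamError(f"bT_hat must be >= 0, got {self.bT_hat}")
        for name in ("C_R", "C_C"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ParamError(f"{name} must be in [0, 1), got {v}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LumpedParams":
        return cls(**d)


@dataclass(frozen=True)
class UnitConventions:
    """Free unit choices made when expanding lumped parameters.

    ``delta_tox`` defaults to ``gamma`` (set in ``__post_init__``), which
    makes ``b_T == bT_hat`` under unit degradation rates.
    ``toxin_production_scale`` multiplies ``pi_T * d_tox`` in the toxin
    production grid; 1.0 gives the concentration normalisation in which a
    fully producing lattice yields concentration ``pi_T``.
    """

    gamma: float = DEFAULT_GAMMA
    d_cue: float = 1.0
    d_tox: float = 1.0
    delta_tox: float | None = None
    toxin_production_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.d_cue <= 0 or self.d_tox <= 0:
            raise ParamError("gamma, d_cue and d_tox must be positive")
        if self.delta_tox is None:
            object.__setattr__(self, "delta_tox", self.gamma)
        if self.delta_tox <= 0:
            raise ParamError("delta_tox must be positive")
        if self.toxin_production_scale <= 0:
            raise ParamError("toxin_production_scale must be positive")


@dataclass(frozen=True)
class RawParams:
    """Full rate set actually consumed by the dynamics.

    Produced from :class:`LumpedParams` by :func:`expand_lumped`; the
    mutation block carries the fixed defaults and can be overridden (e.g.
    zeroed for phenotypic experiments with constructed strains).
    """

    # cue molecule
    p_cue: float
    d_cue: float
    D_cue: float
    # toxin molecule
    d_tox: float
    D_tox: float
    tox_production_scale: float
    # demography
    delta: float
    gamma: float
    delta_tox: float
    # costs
    C_T0: float
    b_T: float
    C_R: float
    C_C: float
    # timing
    tau_delay: int = 50
    # mutation block
    mu_gain: float = 5e-5
    mu_loss: float = 5e-4
    mu: float = 5e-4
    p_largemut: float = 1e-3
    sigma_mu: float = 0.05

    def without_mutations(self) -> "RawParams":
        """Copy with all mutation probabilities set to zero."""
        return replace(self, mu_gain=0.0, mu_loss=0.0, mu=0.0)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RawParams":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "RawParams":
        return cls.from_dict(json.loads(s))


def expand_lumped(
    lumped: LumpedParams, conventions: UnitConventions | None = None
) -> RawParams:
    """Expand the six lumped parameters into the full raw rate set.

    Diffusion rates follow from ``L = sqrt(2 D / d)``, the basal death
    probability from ``delta = gamma * R0_inv``, and the toxin cost slope
    from ``bT_hat = gamma * d_tox * b_T / delta_tox``.
    """
    conv = conventions or UnitConventions()
    D_cue = lumped.L_cue**2 * conv.d_cue / 2.0
    D_tox = lumped.L_tox**2 * conv.d_tox / 2.0
    delta = conv.gamma * lumped.R0_inv
    b_T = lumped.bT_hat * conv.delta_tox / (conv.gamma * conv.d_tox)
    return RawParams(
        p_cue=conv.d_cue,  # fully occupied lattice -> cue concentration 1
        d_cue=conv.d_cue,
        D_cue=D_cue,
        d_tox=conv.d_tox,
        D_tox=D_tox,
        tox_production_scale=conv.toxin_production_scale,
        delta=delta,
        gamma=conv.gamma,
        delta_tox=conv.delta_tox,
        C_T0=0.01,
        b_T=b_T,
        C_R=lumped.C_R,
        C_C=lumped.C_C,
    )


def lump(raw: RawParams) -> LumpedParams:
    """Collapse a raw rate set back to its lumped parameters."""
    return LumpedParams(
        L_cue=math.sqrt(2.0 * raw.D_cue / raw.d_cue),
        L_tox=math.sqrt(2.0 * raw.D_tox / raw.d_tox),
        R0_inv=raw.delta / raw.gamma,
        bT_hat=raw.gamma * raw.d_tox * raw.b_T / raw.delta_tox,
        C_R=raw.C_R,
        C_C=raw.C_C,
    )


def sample_sweep(
    n: int,
    rng: np.random.Generator,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> list[LumpedParams]:
    """Draw ``n`` parameter-sweep points, each coordinate independent uniform.

    ``ranges`` maps lumped-parameter names to (lo, hi) intervals and
    defaults to :data:`SWEEP_RANGES`.  Degenerate intervals ``(a, a)`` are
    allowed; inverted ones are not.
    """
    if n < 1:
        raise ParamError(f"n must be >= 1, got {n}")
    ranges = dict(SWEEP_RANGES if ranges is None else ranges)
    names = [f.name for f in fields(LumpedParams)]
    unknown = set(ranges) - set(names)
    if unknown:
        raise ParamError(f"unknown sweep parameters: {sorted(unknown)}")
    for name, (lo, hi) in ranges.items():
        if hi < lo:
            raise ParamError(f"inverted interval for {name}: [{lo}, {hi}]")
    out = []
    for _ in range(n):
        draw = {}
        for name in names:
            lo, hi = ranges.get(name, SWEEP_RANGES[name])
            draw[name] = lo if hi == lo else lo + (hi - lo) * rng.random()
        out.append(LumpedParams(**draw))
    return out


def carrying_capacity(R0_inv: float) -> float:
    """Equilibrium occupied fraction of a cost-free sensitive population.

    ``K = 1 - R0_inv``; populations with ``R0_inv >= 1`` cannot persist.
    """
    if not 0.0 <= R0_inv:
        raise ParamError(f"R0_inv must be >= 0, got {R0_inv}")
    if R0_inv >= 1.0:
        raise NonviablePopulationError(
            f"R0_inv = {R0_inv} >= 1: expected lifetime offspring < 1"
        )
    return 1.0 - R0_inv
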
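"""Whole-run drivers: growth regimes and experimental protocols.

Three growth regimes are supported:

``FIXED``
    an undisturbed habitat, started from 10% random occupancy, iterated
    for a fixed number of steps;
``SERIAL``
    serial-transfer cycles: after each growth phase a small random sample
    of founder cells is moved to a fresh, empty lattice (cycle lengths
    either fixed or geometrically distributed with the same mean);
``WELL_MIXED``
    as FIXED but with all cell positions randomised each step, destroying
    spatial structure.

On top of the regimes, two phenotypic experiments with constructed
(mutation-free) strains are provided: growth of a single-founder colony
(to measure the density-cue profile of an expanding colony) and
strip-invasion experiments (to measure front speeds between strains).
"""

from __future__ import annotations

import enum
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import dynamics, fields
from .dynamics import (
    Allele,
    GENOTYPE_LABELS,
    Genotype,
    Lattice,
    StepOptions,
    VIABLE_PAIRS,
)
from .params import LumpedParams, RawParams, UnitConventions, expand_lumped

__all__ = [
    "Regime",
    "TransferMode",
    "RunConfig",
    "RunRecord",
    "ColonyResult",
    "run_fixed_habitat",
    "serial_transfer_event",
    "run_serial_transfer",
    "run_single_colony",
    "run_invasion_experiment",
    "resident_carrying_capacity",
]


class Regime(str, enum.Enum):
    FIXED = "FIXED"
    SERIAL = "SERIAL"
    WELL_MIXED = "WELL_MIXED"


class TransferMode(str, enum.Enum):
    FIXED_INTERVAL = "FIXED_INTERVAL"
    GEOMETRIC = "GEOMETRIC"


class ExtinctionError(RuntimeError):
    """The population died out where the protocol cannot continue."""


@dataclass(frozen=True)
class RunConfig:
    """Settings of one simulation run (regime, sizes, noise, seed)."""

    N: int = 512
    regime: Regime = Regime.FIXED
    total_steps: int = 400_000
    total_cycles: int = 800
    tau_transfer: int = 500
    n_founders: int = 1000
    transfer_mode: TransferMode = TransferMode.FIXED_INTERVAL
    sigma_noise: float = 0.0
    lag_steps: int = 0
    record_every: int = 100
    init_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "regime", Regime(self.regime))
        object.__setattr__(self, "transfer_mode", TransferMode(self.transfer_mode))
        if self.N < 3:
            raise ValueError("N must be >= 3")
        for name in ("total_steps", "total_cycles", "tau_transfer",
                     "n_founders", "record_every"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_founders > self.N * self.N:
            raise ValueError("n_founders exceeds lattice size")
        if self.sigma_noise < 0 or self.lag_steps < 0:
            raise ValueError("sigma_noise and lag_steps must be >= 0")
        if not 0 < self.init_fraction <= 1:
            raise ValueError("init_fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regime"] = self.regime.value
        d["transfer_mode"] = self.transfer_mode.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def step_options(self, mutations: bool = True) -> StepOptions:
        return StepOptions(
            sigma_noise=self.sigma_noise,
            lag_steps=self.lag_steps,
            well_mixed=self.regime is Regime.WELL_MIXED,
            mutations=mutations,
        )


# --------------------------------------------------------------------------
# Recording
# --------------------------------------------------------------------------

#: Gene-pair labels of regulating genotypes (>= one Reg allele).
REG_LABELS = tuple(
    GENOTYPE_LABELS[(int(t), int(r))]
    for t, r in VIABLE_PAIRS
    if Allele.REG in (t, r)
)


def record_state(lattice: Lattice, cue: np.ndarray | None = None) -> dict:
    """One time-series row: genotype, phenotype and activity counts.

    Phenotype classes are killer (phi_T = 1), resistant (phi_R = 1 and
    phi_T = 0) and sensitive (neither).  For each regulating genotype the
    cells are split into *active* (at least one regulated gene currently
    expressed) and *inactive*.
    """
    occ = lattice.occupied
    row: dict = {"step": lattice.step_count, "pop": int(occ.sum())}
    key = lattice.genotype_key()
    for (t, r), label in GENOTYPE_LABELS.items():
        row[f"n{label}"] = int(np.count_nonzero(occ & (key == 3 * t + r)))
    killer = occ & lattice.phi_t
    resistant = occ & lattice.phi_r & ~lattice.phi_t
    row["n_K"] = int(killer.sum())
    row["n_R"] = int(resistant.sum())
    row["n_S"] = row["pop"] - row["n_K"] - row["n_R"]
    row["mean_pi_T_killers"] = (
        float(lattice.pi_t[killer].mean()) if row["n_K"] else np.nan
    )
    tg, rg = lattice.toxin_gene, lattice.resist_gene
    reg_expressed = ((tg == Allele.REG) & lattice.phi_t) | (
        (rg == Allele.REG) & lattice.phi_r
    )
    for (t, r), label in GENOTYPE_LABELS.items():
        if Allele.REG not in (Allele(t), Allele(r)):
            continue
        members = occ & (key == 3 * t + r)
        row[f"active{label}"] = int(np.count_nonzero(members & reg_expressed))
    if cue is not None:
        row["mean_cue_occupied"] = (
            float(cue[occ].mean()) if row["pop"] else np.nan
        )
    return row


@dataclass
class RunRecord:
    """Time series plus final state and provenance of one run."""

    config: RunConfig
    lumped: LumpedParams
    seed: int
    timeseries: pd.DataFrame
    final_lattice: Lattice | None = None
    extinct: bool = False
    cycle_ends: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def final_step(self) -> int:
        return int(self.timeseries["step"].iloc[-1])


def _rng_for(config: RunConfig, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *extra]))


def _raw_for(
    lumped: LumpedParams, conventions: UnitConventions | None
) -> RawParams:
    return expand_lumped(lumped, conventions)


# --------------------------------------------------------------------------
# Fixed habitat / well-mixed
# --------------------------------------------------------------------------

def run_fixed_habitat(
    lumped: LumpedParams,
    config: RunConfig,
    conventions: UnitConventions | None = None,
) -> RunRecord:
    """Undisturbed (or well-mixed) habitat run from 10% random occupancy."""
    if config.regime not in (Regime.FIXED, Regime.WELL_MIXED):
        raise ValueError(f"regime must be FIXED or WELL_MIXED, got {config.regime}")
    raw = _raw_for(lumped, conventions)
    rng = _rng_for(config)
    lattice = dynamics.initialise_lattice(config.N, config.init_fraction, rng)
    options = config.step_options()
    rows = [record_state(lattice)]
    extinct = False
    for _ in range(config.total_steps):
        info = dynamics.step(lattice, raw, rng, options)
        if lattice.step_count % config.record_every == 0:
            rows.append(record_state(lattice, info["cue"]))
        if lattice.popsize == 0:
            extinct = True
            rows.append(record_state(lattice))
            break
    return RunRecord(
        config=config,
        lumped=lumped,
        seed=config.seed,
        timeseries=pd.DataFrame(rows),
        final_lattice=lattice,
        extinct=extinct,
    )


# --------------------------------------------------------------------------
# Serial transfers
# --------------------------------------------------------------------------

def serial_transfer_event(
    lattice: Lattice, n_founders: int, rng: np.random.Generator
) -> Lattice:
    """Sample founders and re-seed them on a fresh, empty lattice.

    ``min(n_founders, popsize)`` cells are drawn uniformly without
    replacement and placed at distinct uniform-random sites of a new
    lattice; genotypes are carried over unchanged while per-cell delay and
    lag bookkeeping is reset.
    """
    pop = lattice.popsize
    if pop == 0:
        raise ExtinctionError("cannot transfer an extinct population")
    k = min(n_founders, pop)
    occ_i, occ_j = np.nonzero(lattice.occupied)
    chosen = rng.choice(pop, size=k, replace=False)
    src_i, src_j = occ_i[chosen], occ_j[chosen]
    N = lattice.N
    dest = rng.choice(N * N, size=k, replace=False)
    di, dj = np.unravel_index(dest, (N, N))
    out = Lattice(N)
    out.step_count = lattice.step_count
    out.occupied[di, dj] = True
    out.toxin_gene[di, dj] = lattice.toxin_gene[src_i, src_j]
    out.resist_gene[di, dj] = lattice.resist_gene[src_i, src_j]
    out.pi_t[di, dj] = lattice.pi_t[src_i, src_j]
    out.theta[di, dj] = lattice.theta[src_i, src_j]
    out.strain[di, dj] = lattice.strain[src_i, src_j]
    out.fresh[di, dj] = True
    return out


def run_serial_transfer(
    lumped: LumpedParams,
    config: RunConfig,
    conventions: UnitConventions | None = None,
) -> RunRecord:
    """Serial-transfer run: growth cycles separated by founder sampling.

    Cycle lengths are ``tau_transfer`` steps (FIXED_INTERVAL) or drawn
    independently from a geometric distribution with that mean (GEOMETRIC,
    minimum one step).  End-of-cycle abundances are recorded for every
    cycle; within-cycle rows are recorded at ``record_every``.
    """
    if config.regime is not Regime.SERIAL:
        raise ValueError(f"regime must be SERIAL, got {config.regime}")
    raw = _raw_for(lumped, conventions)
    rng = _rng_for(config)
    lattice = dynamics.initialise_lattice(config.N, config.init_fraction, rng)
    options = config.step_options()
    rows = [record_state(lattice)]
    end_rows = []
    extinct = False
    for cycle in range(config.total_cycles):
        if config.transfer_mode is TransferMode.GEOMETRIC:
            length = int(rng.geometric(1.0 / config.tau_transfer))
        else:
            length = config.tau_transfer
        for _ in range(length):
            info = dynamics.step(lattice, raw, rng, options)
            if lattice.step_count % config.record_every == 0:
                rows.append(record_state(lattice, info["cue"]))
            if lattice.popsize == 0:
                extinct = True
                break
        end_row = record_state(lattice)
        end_row["cycle"] = cycle
        end_row["cycle_length"] = length
        end_rows.append(end_row)
        if extinct:
            break
        lattice = serial_transfer_event(lattice, config.n_founders, rng)
    return RunRecord(
        config=config,
        lumped=lumped,
        seed=config.seed,
        timeseries=pd.DataFrame(rows),
        final_lattice=lattice,
        extinct=extinct,
        cycle_ends=pd.DataFrame(end_rows),
    )


# --------------------------------------------------------------------------
# Single-colony growth
# --------------------------------------------------------------------------

@dataclass
class ColonyResult:
    """Per-step colony geometry/edge-cue series and final radial profile."""

    edge_series: pd.DataFrame
    final_profile: pd.DataFrame
    record: RunRecord
    attempts: int = 1


def colony_edge_mask(occupied: np.ndarray) -> np.ndarray:
    """Occupied sites on the outer boundary of the main colony.

    The colony is the largest 8-connected component of occupied sites; its
    edge cells are the component members with at least one empty Moore
    neighbour in the *exterior* (interior holes do not count).  Assumes
    the colony does not wrap around the periodic boundary.
    """
    structure = np.ones((3, 3), dtype=bool)
    labels, n = ndimage.label(occupied, structure=structure)
    if n == 0:
        return np.zeros_like(occupied)
    sizes = ndimage.sum_labels(occupied, labels, index=np.arange(1, n + 1))
    comp = labels == (1 + int(np.argmax(sizes)))
    exterior = ~ndimage.binary_fill_holes(comp)
    return comp & ndimage.binary_dilation(exterior, structure=structure)


def radial_cue_profile(
    cue: np.ndarray, centre: tuple[float, float], bin_width: float = 1.0
) -> pd.DataFrame:
    """Mean cue concentration in concentric radius bins around ``centre``."""
    N = cue.shape[0]
    ii, jj = np.indices((N, N))
    r = np.hypot(ii - centre[0], jj - centre[1])
    bins = np.floor(r / bin_width).astype(int)
    df = pd.DataFrame({"bin": bins.ravel(), "cue": cue.ravel()})
    prof = df.groupby("bin")["cue"].agg(["mean", "count"]).reset_index()
    prof["radius"] = (prof["bin"] + 0.5) * bin_width
    return prof[["radius", "mean", "count"]].rename(columns={"mean": "cue"})


def run_single_colony(
    lumped: LumpedParams,
    config: RunConfig,
    founder: Genotype,
    conventions: UnitConventions | None = None,
    max_attempts: int = 20,
) -> ColonyResult:
    """Grow one colony from a single founder cell at the lattice centre.

    Runs for one transfer-cycle length (``tau_transfer`` steps) without
    mutations.  At every recorded step the colony radius ``sqrt(area/pi)``
    and the mean cue concentration over the colony's outer-edge cells are
    measured; the radial cue profile is returned for the final state.  If
    the founder lineage dies out before the cycle ends, the run is retried
    on the next seed substream (up to ``max_attempts``).
    """
    raw = _raw_for(lumped, conventions).without_mutations()
    options = config.step_options(mutations=False)
    centre = (config.N // 2, config.N // 2)
    ii, jj = np.indices((config.N, config.N))
    r_grid = np.hypot(ii - centre[0], jj - centre[1])
    last_error: ExtinctionError | None = None
    for attempt in range(max_attempts):
        rng = _rng_for(config, attempt)
        lattice = Lattice(config.N)
        lattice.place(
            np.array([centre[0] * config.N + centre[1]]), founder, strain=1
        )
        rows = []
        edge_rows = []
        cue = None
        died = False
        for _ in range(config.tau_transfer):
            info = dynamics.step(lattice, raw, rng, options)
            cue = info["cue"]
            if lattice.popsize == 0:
                died = True
                break
            if lattice.step_count % config.record_every == 0:
                rows.append(record_state(lattice, cue))
                edge = colony_edge_mask(lattice.occupied)
                n_edge = int(edge.sum())
                area = lattice.popsize
                if n_edge:
                    # geometric rim radius and the unbiased cue level there
                    # (mean over the whole annulus, occupied or not)
                    r_geo = float(r_grid[edge].mean())
                    ring = (r_grid >= r_geo - 0.5) & (r_grid < r_geo + 0.5)
                    ring_cue = float(cue[ring].mean())
                    edge_cue = float(cue[edge].mean())
                else:
                    r_geo = ring_cue = edge_cue = np.nan
                edge_rows.append(
                    {
                        "step": lattice.step_count,
                        "area": area,
                        "radius": float(np.sqrt(area / np.pi)),
                        "radius_geo": r_geo,
                        "n_edge": n_edge,
                        "edge_cue_mean": edge_cue,
                        "ring_cue_mean": ring_cue,
                    }
                )
        if died:
            last_error = ExtinctionError(
                f"founder lineage died (attempt {attempt + 1})"
            )
            continue
        record = RunRecord(
            config=config,
            lumped=lumped,
            seed=config.seed,
            timeseries=pd.DataFrame(rows),
            final_lattice=lattice,
            metadata={"founder": founder.label, "attempt": attempt + 1},
        )
        profile = radial_cue_profile(cue, centre)
        return ColonyResult(
            edge_series=pd.DataFrame(edge_rows),
            final_profile=profile,
            record=record,
            attempts=attempt + 1,
        )
    raise last_error or ExtinctionError("colony never established")


# --------------------------------------------------------------------------
# Invasion experiments
# --------------------------------------------------------------------------

def resident_carrying_capacity(
    resident: Genotype, raw: RawParams, tol: float = 1e-10
) -> float:
    """Self-consistent equilibrium density of a clonal resident population.

    Mean-field balance gives ``K = 1 - delta / (gamma * R)`` where ``R``
    is the resident's reproductive fitness at the phenotype it expresses
    when the cue concentration equals ``K`` itself; for regulating strains
    the fixed point is found by iteration.  Recovers ``K_S = 1 -
    delta/gamma`` for sensitives and ``K_R = 1 - delta/(gamma (1 - C_R))``
    for constitutive resistants.
    """
    def fitness_at(cue: float) -> float:
        has_reg = Allele.REG in (resident.toxin_gene, resident.resistance_gene)
        above = has_reg and resident.theta is not None and cue >= resident.theta
        phi_t = resident.toxin_gene == Allele.ON or (
            resident.toxin_gene == Allele.REG and above
        )
        phi_r = resident.resistance_gene == Allele.ON or (
            resident.resistance_gene == Allele.REG and above
        )
        return float(
            dynamics.reproductive_fitness(
                phi_t, phi_r, has_reg, resident.pi_t, raw
            )
        )

    K = 1.0 - raw.delta / raw.gamma
    for _ in range(200):
        R = fitness_at(K)
        if R <= raw.delta / raw.gamma:
            return 0.0
        K_new = 1.0 - raw.delta / (raw.gamma * R)
        if abs(K_new - K) < tol:
            return K_new
        K = 0.5 * (K + K_new)
    return K


def make_invasion_lattice(
    invader: Genotype,
    resident: Genotype,
    N: int,
    K_resident: float,
    rng: np.random.Generator,
    strip_width: int = 20,
) -> Lattice:
    """Full-height strip of invader cells in a resident background.

    Columns ``0..strip_width-1`` are fully occupied by the invader
    (strain label 1); every other site independently holds a resident
    (strain label 2) with probability ``K_resident``.
    """
    if strip_width >= N:
        raise ValueError("strip width must be smaller than the lattice side")
    lattice = Lattice(N)
    ii, jj = np.indices((N, N))
    strip = jj < strip_width
    lattice.place(np.flatnonzero(strip.ravel()), invader, strain=1)
    background = ~strip & (rng.random((N, N)) < K_resident)
    lattice.place(np.flatnonzero(background.ravel()), resident, strain=2)
    return lattice


def run_invasion_experiment(
    invader: Genotype,
    resident: Genotype,
    lumped: LumpedParams,
    config: RunConfig,
    conventions: UnitConventions | None = None,
    strip_width: int = 20,
) -> pd.DataFrame:
    """Strip-invasion experiment between two constructed strains.

    Runs ``config.total_steps`` steps without mutations and returns the
    per-step strain counts (columns ``step``, ``n_invader``,
    ``n_resident``) with the resident equilibrium density ``K_resident``
    attached as ``DataFrame.attrs``.
    """
    raw = _raw_for(lumped, conventions).without_mutations()
    rng = _rng_for(config)
    K_res = resident_carrying_capacity(resident, raw)
    lattice = make_invasion_lattice(
        invader, resident, config.N, K_res, rng, strip_width
    )
    options = config.step_options(mutations=False)
    rows = [
        {
            "step": 0,
            "n_invader": int((lattice.strain == 1).sum()),
            "n_resident": int((lattice.strain == 2).sum()),
        }
    ]
    for _ in range(config.total_steps):
        dynamics.step(lattice, raw, rng, options)
        rows.append(
            {
                "step": lattice.step_count,
                "n_invader": int(
                    np.count_nonzero(lattice.occupied & (lattice.strain == 1))
                ),
                "n_resident": int(
                    np.count_nonzero(lattice.occupied & (lattice.strain == 2))
                ),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["K_resident"] = K_res
    df.attrs["strip_width"] = strip_width
    return df
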
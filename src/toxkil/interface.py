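"""Configuration files, deterministic fixtures, and run persistence.

Configs are JSON (canonical) or YAML (accepted for authoring) documents
with two sections::

    {
      "lumped": {"L_cue": 6, "L_tox": 6, "R0_inv": 0.125,
                 "bT_hat": 0.072, "C_R": 0.1, "C_C": 0.02},
      "run":    {"N": 512, "regime": "SERIAL", "seed": 1, ...}
    }

Unknown keys are rejected.  Run results are persisted as a directory of
CSV tables plus a JSON metadata file recording the effective config, the
seed and the package version.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import Allele, Genotype, Lattice
from .params import LumpedParams
from .regimes import RunConfig, RunRecord

__all__ = [
    "Config",
    "load_config",
    "save_config",
    "make_fixture",
    "FIXTURE_NAMES",
    "write_run_record",
    "read_run_record",
    "lattice_to_frame",
    "frame_to_lattice",
]


class ConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class Config:
    lumped: LumpedParams
    run: RunConfig

    def to_dict(self) -> dict:
        return {"lumped": self.lumped.to_dict(), "run": self.run.to_dict()}


def _build_config(doc: dict, source: str = "<config>") -> Config:
    if not isinstance(doc, dict):
        raise ConfigError(f"{source}: top level must be a mapping")
    unknown = set(doc) - {"lumped", "run"}
    if unknown:
        raise ConfigError(f"{source}: unknown top-level keys {sorted(unknown)}")
    if "lumped" not in doc:
        raise ConfigError(f"{source}: missing 'lumped' section")
    lumped_keys = {f.name for f in dataclasses.fields(LumpedParams)}
    bad = set(doc["lumped"]) - lumped_keys
    if bad:
        raise ConfigError(f"{source}: unknown lumped keys {sorted(bad)}")
    missing = lumped_keys - set(doc["lumped"])
    if missing:
        raise ConfigError(f"{source}: missing lumped keys {sorted(missing)}")
    run_doc = dict(doc.get("run", {}))
    run_keys = {f.name for f in dataclasses.fields(RunConfig)}
    bad = set(run_doc) - run_keys
    if bad:
        raise ConfigError(f"{source}: unknown run keys {sorted(bad)}")
    try:
        return Config(
            lumped=LumpedParams(**doc["lumped"]), run=RunConfig(**run_doc)
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{source}: {exc}") from exc


def load_config(path: str | Path) -> Config:
    """Load and validate a JSON or YAML config file (defaults filled)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    return _build_config(doc, source=str(path))


def save_config(config: Config, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=1) + "\n")


# --------------------------------------------------------------------------
# Deterministic fixtures
# --------------------------------------------------------------------------

FIXTURE_NAMES = (
    "single_source",
    "uniform_full",
    "checkerboard",
    "strip20",
    "three_colonies",
)

_SENSITIVE = Genotype(Allele.OFF, Allele.OFF)
_KILLER = Genotype(Allele.ON, Allele.ON, pi_t=0.13)
_REG_RESISTANT = Genotype(Allele.OFF, Allele.REG, theta=0.67)
_REG_KILLER = Genotype(Allele.REG, Allele.REG, pi_t=1.0, theta=0.67)


def make_fixture(
    name: str, N: int, rng: np.random.Generator | None = None
) -> Lattice:
    """Deterministic mini-lattices for tests and demonstrations.

    ``single_source``: one sensitive cell at the lattice centre.
    ``uniform_full``: every site occupied by a sensitive cell.
    ``checkerboard``: sensitive cells on the even-parity sites.
    ``strip20``: 20 full columns of a constitutive killer, rest empty.
    ``three_colonies``: three founder cells at mutually equal toroidal
    distances — a sensitive, a regulating resistant and a regulating
    killer (the colony-competition demonstration layout).
    """
    lattice = Lattice(N)
    ii, jj = np.indices((N, N))
    if name == "single_source":
        lattice.place(np.array([(N // 2) * N + N // 2]), _SENSITIVE)
    elif name == "uniform_full":
        lattice.place(np.arange(N * N), _SENSITIVE)
    elif name == "checkerboard":
        lattice.place(np.flatnonzero(((ii + jj) % 2 == 0).ravel()), _SENSITIVE)
    elif name == "strip20":
        if N <= 20:
            raise ValueError("strip20 needs N > 20")
        lattice.place(np.flatnonzero((jj < 20).ravel()), _KILLER, strain=1)
    elif name == "three_colonies":
        third = N // 3
        founders = [
            (0, 0, _SENSITIVE, 1),
            (third, third, _REG_RESISTANT, 2),
            (2 * third, 2 * third, _REG_KILLER, 3),
        ]
        for i, j, g, s in founders:
            lattice.place(np.array([i * N + j]), g, strain=s)
    else:
        raise ValueError(f"unknown fixture {name!r}; know {FIXTURE_NAMES}")
    return lattice


# --------------------------------------------------------------------------
# Lattice and run-record persistence
# --------------------------------------------------------------------------

_LATTICE_COLUMNS = [
    "i", "j", "toxin_gene", "resist_gene", "pi_t", "theta",
    "phi_t", "phi_r", "phi_c", "delay", "strain",
]


def lattice_to_frame(lattice: Lattice) -> pd.DataFrame:
    """One row per occupied site (genotype, phenotype, bookkeeping)."""
    i, j = np.nonzero(lattice.occupied)
    return pd.DataFrame(
        {
            "i": i,
            "j": j,
            "toxin_gene": lattice.toxin_gene[i, j],
            "resist_gene": lattice.resist_gene[i, j],
            "pi_t": lattice.pi_t[i, j],
            "theta": lattice.theta[i, j],
            "phi_t": lattice.phi_t[i, j].astype(int),
            "phi_r": lattice.phi_r[i, j].astype(int),
            "phi_c": lattice.phi_c[i, j].astype(int),
            "delay": lattice.delay[i, j],
            "strain": lattice.strain[i, j],
        }
    )


def frame_to_lattice(df: pd.DataFrame, N: int, step_count: int = 0) -> Lattice:
    lattice = Lattice(N)
    i = df["i"].to_numpy(int)
    j = df["j"].to_numpy(int)
    lattice.occupied[i, j] = True
    lattice.toxin_gene[i, j] = df["toxin_gene"].to_numpy(np.int8)
    lattice.resist_gene[i, j] = df["resist_gene"].to_numpy(np.int8)
    lattice.pi_t[i, j] = df["pi_t"].to_numpy(float)
    lattice.theta[i, j] = df["theta"].to_numpy(float)
    lattice.phi_t[i, j] = df["phi_t"].to_numpy(bool)
    lattice.phi_r[i, j] = df["phi_r"].to_numpy(bool)
    lattice.phi_c[i, j] = df["phi_c"].to_numpy(bool)
    lattice.delay[i, j] = df["delay"].to_numpy(np.int32)
    lattice.strain[i, j] = df["strain"].to_numpy(np.int16)
    lattice.step_count = step_count
    return lattice


def write_run_record(record: RunRecord, out_dir: str | Path) -> None:
    """Persist a run as CSV tables plus JSON metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record.timeseries.to_csv(out / "timeseries.csv", index=False)
    if record.cycle_ends is not None:
        record.cycle_ends.to_csv(out / "cycle_ends.csv", index=False)
    meta = {
        "version": __version__,
        "seed": record.seed,
        "extinct": record.extinct,
        "config": record.config.to_dict(),
        "lumped": record.lumped.to_dict(),
        "metadata": record.metadata,
        "has_final_lattice": record.final_lattice is not None,
        "final_step": (
            record.final_lattice.step_count if record.final_lattice else None
        ),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1) + "\n")
    if record.final_lattice is not None:
        lattice_to_frame(record.final_lattice).to_csv(
            out / "final_lattice.csv", index=False
        )


def read_run_record(out_dir: str | Path) -> RunRecord:
    out = Path(out_dir)
    meta_path = out / "meta.json"
    ts_path = out / "timeseries.csv"
    for p in (meta_path, ts_path):
        if not p.exists():
            raise FileNotFoundError(f"run record at {out} is missing {p.name}")
    meta = json.loads(meta_path.read_text())
    config = RunConfig.from_dict(meta["config"])
    lumped = LumpedParams.from_dict(meta["lumped"])
    cycle_path = out / "cycle_ends.csv"
    cycle_ends = pd.read_csv(cycle_path) if cycle_path.exists() else None
    final = None
    if meta.get("has_final_lattice"):
        lat_path = out / "final_lattice.csv"
        if not lat_path.exists():
            raise FileNotFoundError(
                f"run record at {out} is missing final_lattice.csv"
            )
        final = frame_to_lattice(
            pd.read_csv(lat_path), config.N, meta.get("final_step") or 0
        )
    return RunRecord(
        config=config,
        lumped=lumped,
        seed=meta["seed"],
        timeseries=pd.read_csv(ts_path),
        final_lattice=final,
        extinct=meta["extinct"],
        cycle_ends=cycle_ends,
        metadata=meta.get("metadata", {}),
    )
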
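"""Composition scans, run manifests, staged GROMACS inputs, and replicate
aggregation.

A *scan* replaces a starting lipid by a replacement lipid in fixed fraction
increments (default 20%, giving 6 compositions from 100:0 to 0:100), each
composition simulated ``n_replicates`` times (default 10).  The bundled
experiment file groups eleven such scans into three experiments probing the
compositional changes of ferroptosis: saturated-to-polyunsaturated tails
(SFA:PUFA), PC-to-PE head groups, and plain-to-peroxidized lipids.

Each run's MD inputs are a fixed five-stage sequence of GROMACS parameter
files: energy minimization, position-restrained NVT, position-restrained
NpT, unrestrained NpT, and production (default 10 us).  Actually executing
the engine is out of scope; the pipeline writes valid inputs and aggregates
analyzer outputs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .membrane_builder import MembraneComposition
from .membrane_props import PropertyReport

__all__ = [
    "ScanSpec",
    "ExperimentSpec",
    "RunManifest",
    "Run",
    "generate_scan_compositions",
    "write_mdp_sequence",
    "build_manifest",
    "aggregate_replicates",
    "load_experiments",
    "STAGES",
]

STAGES = ("em", "nvt_posres", "npt_posres", "npt", "production")
MARTINI_DT_PS = 0.02           # 20 fs coarse-grained timestep
TEMPERATURE_K = 310.0
PRESSURE_BAR = 1.0


@dataclass(frozen=True)
class ScanSpec:
    """One composition scan between two lipid species."""

    start_lipid: str
    end_lipid: str
    increment: float = 0.2
    n_replicates: int = 10
    n_per_leaflet: int = 128
    production_time_us: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.increment <= 1):
            raise ValueError("increment must lie in (0, 1]")
        steps = 1.0 / self.increment
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("1/increment must be an integer")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_compositions(self) -> int:
        return round(1.0 / self.increment) + 1

    @property
    def label(self) -> str:
        return f"{self.start_lipid}:{self.end_lipid}"


@dataclass(frozen=True)
class ExperimentSpec:
    name: str
    scans: tuple[ScanSpec, ...]


def generate_scan_compositions(spec: ScanSpec) -> list[MembraneComposition]:
    """Compositions from 100% start lipid to 100% end lipid.

    A 20% increment yields the canonical 6-membrane scan.
    """
    steps = round(1.0 / spec.increment)
    out = []
    for i in range(steps + 1):
        f_end = i / steps
        fractions = {}
        if f_end < 1.0:
            fractions[spec.start_lipid] = 1.0 - f_end
        if f_end > 0.0:
            fractions[spec.end_lipid] = f_end
        out.append(MembraneComposition(fractions))
    return out


def _mdp(lines: dict) -> str:
    return "\n".join(f"{k:<24s}= {v}" for k, v in lines.items()) + "\n"


def write_mdp_sequence(spec: ScanSpec) -> list[tuple[str, str]]:
    """The five staged GROMACS .mdp files as (stage name, text) pairs.

    Thermostat/barostat settings follow standard MARTINI recommendations
    (310 K v-rescale, 1 bar semi-isotropic Parrinello-Rahman, 20 fs step);
    position restraints are active in the two equilibration stages only; the
    production stage integrates ``production_time_us`` (default 10 us).
    """
    common = {
        "integrator": "md",
        "dt": MARTINI_DT_PS,
        "cutoff-scheme": "Verlet",
        "coulombtype": "reaction-field",
        "rcoulomb": 1.1,
        "rvdw": 1.1,
        "tcoupl": "v-rescale",
        "tc-grps": "System",
        "tau-t": 1.0,
        "ref-t": TEMPERATURE_K,
    }
    npt = {
        "pcoupl": "parrinello-rahman",
        "pcoupltype": "semiisotropic",
        "tau-p": 12.0,
        "ref-p": f"{PRESSURE_BAR} {PRESSURE_BAR}",
        "compressibility": "3e-4 3e-4",
    }
    posres = {"define": "-DPOSRES"}
    production_ps = spec.production_time_us * 1e6
    stages = [
        ("em", _mdp({"integrator": "steep", "emtol": 100.0, "emstep": 0.01,
                     "nsteps": 10000, "cutoff-scheme": "Verlet",
                     "coulombtype": "reaction-field", "rcoulomb": 1.1, "rvdw": 1.1})),
        ("nvt_posres", _mdp({**common, **posres, "nsteps": 50000, "pcoupl": "no"})),
        ("npt_posres", _mdp({**common, **posres, **npt, "nsteps": 50000})),
        ("npt", _mdp({**common, **npt, "nsteps": 250000})),
        ("production", _mdp({**common, **npt,
                             "nsteps": int(round(production_ps / MARTINI_DT_PS))})),
    ]
    return stages


@dataclass(frozen=True)
class Run:
    experiment: str
    scan: str
    composition: dict
    replicate: int
    seed: int
    stage_paths: tuple[str, ...]


@dataclass
class RunManifest:
    master_seed: int
    runs: list[Run] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "master_seed": self.master_seed,
            "runs": [
                {
                    "experiment": r.experiment,
                    "scan": r.scan,
                    "composition": r.composition,
                    "replicate": r.replicate,
                    "seed": r.seed,
                    "stage_paths": list(r.stage_paths),
                }
                for r in self.runs
            ],
        }


def build_manifest(experiment: ExperimentSpec, master_seed: int) -> RunManifest:
    """Enumerate every (composition, replicate) run with a distinct seed.

    Seeds are ``(master_seed * 1000003 + run_index) mod 2^31``: deterministic,
    pairwise distinct, and reproducible from the master seed alone.  The seed
    drives both the builder's lateral shuffling and the engine's velocity
    generation.
    """
    manifest = RunManifest(master_seed=master_seed)
    run_index = 0
    for scan in experiment.scans:
        for ci, comp in enumerate(generate_scan_compositions(scan)):
            for rep in range(scan.n_replicates):
                seed = (master_seed * 1000003 + run_index) % (2**31)
                tag = f"{scan.label.replace(':', '-')}/c{ci}/r{rep}"
                manifest.runs.append(
                    Run(
                        experiment=experiment.name,
                        scan=scan.label,
                        composition=comp.fractions,
                        replicate=rep,
                        seed=seed,
                        stage_paths=tuple(f"{tag}/{s}.mdp" for s in STAGES),
                    )
                )
                run_index += 1
    return manifest


def aggregate_replicates(reports: list[PropertyReport]) -> pd.DataFrame:
    """Per-composition mean, standard deviation and n for each property.

    Single-replicate groups report ``sd = NaN`` (undefined) with the mean
    equal to the lone value.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    rows = []
    for r in reports:
        comp = MembraneComposition(r.composition) if r.composition else None
        rows.append({
            "composition": comp.key() if comp else "",
            "area_per_lipid": r.area_per_lipid,
            "width": r.width,
            "curvature": r.curvature,
            "diffusion": r.diffusion,
        })
    df = pd.DataFrame(rows)
    agg = df.groupby("composition", sort=True).agg(["mean", "std", "count"])
    agg.columns = [f"{prop}_{stat}".replace("_count", "_n") for prop, stat in agg.columns]
    n_cols = [c for c in agg.columns if c.endswith("_n")]
    agg["n"] = agg[n_cols[0]]
    agg = agg.drop(columns=n_cols)
    return agg.reset_index()


def load_experiments(path=None) -> list[ExperimentSpec]:
    """Load experiment/scan definitions from YAML (bundled file by default)."""
    if path is None:
        ref = importlib.resources.files("oxmembrane").joinpath("data/experiments.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    defaults = raw.get("defaults", {})
    experiments = []
    for exp in raw["experiments"]:
        scans = tuple(
            ScanSpec(
                start_lipid=start,
                end_lipid=end,
                increment=defaults.get("increment", 0.2),
                n_replicates=defaults.get("n_replicates", 10),
                n_per_leaflet=defaults.get("n_per_leaflet", 128),
                production_time_us=defaults.get("production_time_us", 10.0),
            )
            for start, end in exp["scans"]
        )
        experiments.append(ExperimentSpec(name=exp["name"], scans=scans))
    return experiments
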
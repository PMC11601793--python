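"""Config-driven study drivers: parameter sweeps and convergence checks.

Each driver runs seeded ensembles of microstructure realizations through
the homogenizer and returns a tidy DataFrame (one row per realization),
so every figure is a pure view of a CSV and every row is regenerable
from (config, seed).  The studies mirror the standard elastography
questions: how do the bulk storage/loss moduli and the effective
relaxation time move with fat content, with collagen burden (CPA) and
collagen stiffness, and with both at once at 100 vs 300 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fem import NU_DEFAULT, PeriodicCellProblem, build_mesh
from .fibrosis import FibrosisPattern
from .geometry import UnitCellGeometry, classify_region, distance_fields
from .homogenize import build_microstructure, effective_modulus
from .rheology import MaterialSet
from .steatosis import FatPattern

__all__ = [
    "ExperimentConfig",
    "sweep_steatosis",
    "sweep_fibrosis",
    "sweep_combined",
    "convergence_check",
    "plot_sweep",
    "plot_combined_maps",
]


@dataclass
class ExperimentConfig:
    """Parameters of one study.

    Defaults follow the reference study conditions (300 steatosis /
    100 fibrosis realizations); pass smaller ``n_realizations`` for
    desk-scale runs, at correspondingly wider statistical scatter.
    """

    experiment: str = "steatosis"  # steatosis | fibrosis | combined | convergence
    fat_targets: list = dfield(default_factory=lambda: list(np.linspace(0.0, 0.4, 9)))
    cpa_targets: list = dfield(default_factory=lambda: list(np.linspace(0.01, 0.2, 8)))
    collagen_G: list = dfield(default_factory=lambda: [60e3])
    frequencies: list = dfield(default_factory=lambda: [100.0])
    patterns: list = dfield(default_factory=lambda: ["pattern1", "pattern2"])
    n_realizations: int = 25
    base_seed: int = 0
    mesh: tuple = (40, 80)
    mesh_fine: tuple = (80, 160)
    lobule_diameter: float = 1.0
    vein_radius: float = 0.05
    triad_radius: float = 0.04
    nu: float = NU_DEFAULT

    def __post_init__(self):
        if self.experiment == "combined":
            if max(self.cpa_targets) > 0.10 + 1e-12:
                raise ValueError("combined study is restricted to CPA <= 0.10")
            if max(self.fat_targets) > 0.30 + 1e-12:
                raise ValueError("combined study is restricted to fat <= 0.30")

    @staticmethod
    def from_yaml(path) -> "ExperimentConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        if "mesh" in obj:
            obj["mesh"] = tuple(obj["mesh"])
        if "mesh_fine" in obj:
            obj["mesh_fine"] = tuple(obj["mesh_fine"])
        return ExperimentConfig(**obj)

    def cell(self) -> UnitCellGeometry:
        return UnitCellGeometry(self.lobule_diameter, self.vein_radius, self.triad_radius)


def _ensemble_rows(
    cfg: ExperimentConfig,
    cell,
    fields,
    region,
    problem,
    *,
    fat_target=0.0,
    cpa_target=0.0,
    fat_pattern=FatPattern.P1_CENTRAL,
    fibrosis_pattern=FibrosisPattern.P1_PORTAL_PORTAL,
    materials: MaterialSet,
    frequency: float,
    extra: dict | None = None,
) -> list[dict]:
    rows = []
    for i in range(cfg.n_realizations):
        seed = cfg.base_seed + i
        micro = build_microstructure(
            fat_target, cpa_target, seed=seed, cell=cell,
            fat_pattern=fat_pattern, fibrosis_pattern=fibrosis_pattern,
            fields=fields, region=region,
        )
        res = effective_modulus(micro, materials, frequency, problem=problem)
        row = {
            "seed": seed,
            "pattern": (
                fat_pattern.value if cpa_target == 0 else fibrosis_pattern.value
            ),
            "fat_target": fat_target,
            "fat_realized": res.metadata.get("fat_realized", 0.0),
            "cpa_target": cpa_target,
            "cpa_realized": res.metadata.get("cpa_realized", 0.0),
            "collagen_G_Pa": materials.collagen.parameters["G0"],
            "freq_Hz": frequency,
            "Gp_Pa": res.G_eff.storage,
            "Gpp_Pa": res.G_eff.loss,
            "tau_s": res.tau_eff,
        }
        row.update(extra or {})
        rows.append(row)
    return rows


def _setup(cfg: ExperimentConfig):
    cell = cfg.cell()
    fields = distance_fields(cell)
    region = classify_region(cell)
    problem = PeriodicCellProblem(build_mesh(*cfg.mesh, cell), nu=cfg.nu)
    return cell, fields, region, problem


def sweep_steatosis(cfg: ExperimentConfig, out_dir=None) -> pd.DataFrame:
    """Moduli and relaxation time vs mean fat content, both fat patterns."""
    cell, fields, region, problem = _setup(cfg)
    materials = MaterialSet.default()
    rows = []
    for freq in cfg.frequencies:
        for pat in cfg.patterns:
            for fat in cfg.fat_targets:
                rows += _ensemble_rows(
                    cfg, cell, fields, region, problem,
                    fat_target=fat, fat_pattern=FatPattern(f"{pat}"),
                    materials=materials, frequency=freq,
                )
    df = pd.DataFrame(rows)
    if out_dir:
        df.to_csv(Path(out_dir) / "steatosis_sweep.csv", index=False)
    return df


def sweep_fibrosis(cfg: ExperimentConfig, out_dir=None) -> pd.DataFrame:
    """Moduli and relaxation time vs CPA x collagen modulus x pattern."""
    cell, fields, region, problem = _setup(cfg)
    rows = []
    for freq in cfg.frequencies:
        for Gc in cfg.collagen_G:
            materials = MaterialSet.default(collagen_G=Gc)
            for pat in cfg.patterns:
                for cpa_t in cfg.cpa_targets:
                    rows += _ensemble_rows(
                        cfg, cell, fields, region, problem,
                        cpa_target=cpa_t,
                        fibrosis_pattern=FibrosisPattern(f"{pat}"),
                        materials=materials, frequency=freq,
                    )
    df = pd.DataFrame(rows)
    if out_dir:
        df.to_csv(Path(out_dir) / "fibrosis_sweep.csv", index=False)
    return df


def sweep_combined(cfg: ExperimentConfig, out_dir=None) -> pd.DataFrame:
    """Combined steatosis + fibrosis maps over (fat, CPA) at each frequency.

    Collagen is deposited first; the Pattern-1 fat target is renormalized
    by 1/(1-CPA) on the remaining parenchyma.  The matrix is the
    power-law (springpot) tissue model, making the frequency dependence
    nontrivial; CPA stays <= 10% so bridging (where the two fibrosis
    patterns diverge) never enters.
    """
    cell, fields, region, problem = _setup(cfg)
    materials = MaterialSet.powerlaw_matrix(collagen_G=cfg.collagen_G[0])
    rows = []
    for freq in cfg.frequencies:
        for cpa_t in cfg.cpa_targets:
            for fat in cfg.fat_targets:
                rows += _ensemble_rows(
                    cfg, cell, fields, region, problem,
                    fat_target=fat, cpa_target=cpa_t,
                    materials=materials, frequency=freq,
                )
    df = pd.DataFrame(rows)
    if out_dir:
        df.to_csv(Path(out_dir) / "combined_sweep.csv", index=False)
    return df


def cpa_band(df: pd.DataFrame, lo: float, hi: float) -> pd.DataFrame:
    """Rows whose realized CPA falls in [lo, hi] (cross-section bands)."""
    return df[(df.cpa_realized >= lo) & (df.cpa_realized <= hi)]


_CONVERGENCE_SCENARIOS = {
    "steatosis": dict(fat_target=0.20, cpa_target=0.0),
    "fibrosis": dict(fat_target=0.0, cpa_target=0.10),
    "combined": dict(fat_target=0.15, cpa_target=0.10),
}


def convergence_check(
    cfg: ExperimentConfig,
    scenarios: list[str] | None = None,
    frequency: float = 100.0,
) -> pd.DataFrame:
    """Ensemble-mean modulus on the working vs refined mesh.

    Reports, per scenario, the relative difference of the ensemble-mean
    complex-modulus magnitudes between ``cfg.mesh`` and ``cfg.mesh_fine``.
    """
    cell = cfg.cell()
    fields = distance_fields(cell)
    region = classify_region(cell)
    materials = MaterialSet.default()
    problems = {
        sz: PeriodicCellProblem(build_mesh(*sz, cell), nu=cfg.nu)
        for sz in (tuple(cfg.mesh), tuple(cfg.mesh_fine))
    }
    out = []
    for name in scenarios or list(_CONVERGENCE_SCENARIOS):
        spec = _CONVERGENCE_SCENARIOS[name]
        means = {}
        for sz, problem in problems.items():
            rows = _ensemble_rows(
                cfg, cell, fields, region, problem,
                fat_target=spec["fat_target"], cpa_target=spec["cpa_target"],
                materials=materials, frequency=frequency,
            )
            d = pd.DataFrame(rows)
            means[sz] = complex(d.Gp_Pa.mean(), d.Gpp_Pa.mean())
        coarse, fine = means[tuple(cfg.mesh)], means[tuple(cfg.mesh_fine)]
        out.append(
            {
                "scenario": name,
                "n": cfg.n_realizations,
                "Gp_coarse_Pa": coarse.real,
                "Gpp_coarse_Pa": coarse.imag,
                "Gp_fine_Pa": fine.real,
                "Gpp_fine_Pa": fine.imag,
                "rel_diff_pct": abs(abs(coarse) - abs(fine)) / abs(fine) * 100.0,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# plotting: pure views of the sweep tables
# ---------------------------------------------------------------------------


def plot_sweep(df: pd.DataFrame, x: str = "fat_realized", tau: bool = False):
    """Storage (circles) and loss or relaxation time (dots) vs a sweep axis."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {"pattern1": "tab:red", "pattern2": "tab:blue"}
    for pat, sub in df.groupby("pattern"):
        c = colors.get(pat, "k")
        ax.plot(sub[x] * 100, sub.Gp_Pa / 1e3, "o", mfc="none", color=c,
                label=f"{pat} storage")
        if tau:
            ax2 = ax.twinx()
            ax2.plot(sub[x] * 100, sub.tau_s * 1e3, ".", color=c)
            ax2.set_ylabel("relaxation time (ms)")
        else:
            ax.plot(sub[x] * 100, sub.Gpp_Pa / 1e3, ".", color=c,
                    label=f"{pat} loss")
    ax.set_xlabel(f"{x} (%)")
    ax.set_ylabel("modulus (kPa)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_combined_maps(df: pd.DataFrame, frequency: float = 100.0):
    """Contour maps of mean storage/loss moduli over (fat, CPA)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sub = df[df.freq_Hz == frequency]
    piv_p = sub.pivot_table(index="cpa_target", columns="fat_target", values="Gp_Pa")
    piv_pp = sub.pivot_table(index="cpa_target", columns="fat_target", values="Gpp_Pa")
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, piv, title in zip(axes, (piv_p, piv_pp), ("storage G'", "loss G''")):
        cs = ax.contourf(piv.columns * 100, piv.index * 100, piv.values / 1e3, 12)
        fig.colorbar(cs, ax=ax, label="kPa")
        ax.set_xlabel("fat (%)")
        ax.set_ylabel("CPA (%)")
        ax.set_title(f"{title} at {frequency:g} Hz")
    fig.tight_layout()
    return fig
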
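"""End-to-end synthetic experiments comparing two genotype populations.

Orchestrates the library stages into two reproducible experiments:

* **physiology** — generate spike responses for two synthetic genotypes
  (e.g. wild-type vs mutant with elevated null-direction spiking), run
  quality control, DSI gating, ooDSGC isolation, per-cell tuning metrics,
  subtype clustering, and two-sample KS comparisons of width / strength / Δϕ
  between genotypes;
* **mosaic** — generate fields of soma mosaics per synthetic animal per
  genotype, score the Voronoi domain regularity index, and compare per-animal
  means against a density-matched random-array null envelope.

All stages draw their randomness from per-stage children of a single master
seed, so a run is reproducible end to end.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from retinads import __version__
from retinads.classify import assign_subtypes, compare_populations, gate_dsgc, isolate_oods, qc_filter
from retinads.mosaic import per_animal_summary, random_null, voronoi_domains
from retinads.synthetic import (
    StimulusProtocol,
    SyntheticCellParams,
    SyntheticTruth,
    generate_mosaic,
    generate_population,
)
from retinads.tuning import compute_dsi, compute_metrics, compute_tuning_curve

__all__ = [
    "PhysiologyGenotypeSpec",
    "MosaicGenotypeSpec",
    "RunConfig",
    "build_truth",
    "run_physiology_experiment",
    "run_mosaic_experiment",
]

CARDINALS = (0.0, 90.0, 180.0, 270.0)


@dataclass
class PhysiologyGenotypeSpec:
    """Generator parameters for one genotype's RGC population."""

    n_cells: int = 100
    ds_fraction: float = 0.5
    gain: float = 30.0
    null_rate: float = 0.5
    kappa_choices: tuple[float, ...] = (1.0, 2.0, 4.0)
    off_gain_ratio: float = 1.0
    nonds_gain: float = 5.0
    pref_dir_jitter_sd_deg: float = 10.0
    on_off_delta_sd_deg: float = 10.0


@dataclass
class MosaicGenotypeSpec:
    """Generator parameters for one genotype's soma mosaics."""

    process: str = "hardcore"
    density_cells_mm2: float = 1000.0
    d_min_um: float = 8.0
    jitter_sd_um: float = 3.0


@dataclass
class RunConfig:
    """Configuration of a full synthetic experiment (YAML round-trippable)."""

    name: str = "experiment"
    seed: int = 0
    contrasts_pct: tuple[float, ...] = (150.0, 300.0)
    n_trials: int = 8
    physiology_genotypes: dict[str, PhysiologyGenotypeSpec] = field(
        default_factory=lambda: {
            "wildtype": PhysiologyGenotypeSpec(),
            "mutant": PhysiologyGenotypeSpec(null_rate=6.0),
        }
    )
    mosaic_genotypes: dict[str, MosaicGenotypeSpec] = field(
        default_factory=lambda: {
            "wildtype": MosaicGenotypeSpec(process="lattice_jitter"),
            "mutant": MosaicGenotypeSpec(process="hardcore"),
        }
    )
    n_animals: int = 3
    n_fields: int = 3
    field_size_um: float = 500.0
    null_sims: int = 99

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        kwargs = dict(raw)
        if "physiology_genotypes" in kwargs:
            kwargs["physiology_genotypes"] = {
                k: PhysiologyGenotypeSpec(**_tupled(v)) for k, v in kwargs["physiology_genotypes"].items()
            }
        if "mosaic_genotypes" in kwargs:
            kwargs["mosaic_genotypes"] = {
                k: MosaicGenotypeSpec(**v) for k, v in kwargs["mosaic_genotypes"].items()
            }
        if "contrasts_pct" in kwargs:
            kwargs["contrasts_pct"] = tuple(kwargs["contrasts_pct"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(json.loads(json.dumps(asdict(self)))))


def _tupled(spec: Mapping[str, Any]) -> dict[str, Any]:
    out = dict(spec)
    if "kappa_choices" in out:
        out["kappa_choices"] = tuple(out["kappa_choices"])
    return out


# ---------------------------------------------------------------------------
# population construction
# ---------------------------------------------------------------------------

def build_truth(
    spec: PhysiologyGenotypeSpec,
    protocol: StimulusProtocol,
    seed: int,
    genotype: str = "",
) -> SyntheticTruth:
    """Draw per-cell ground-truth parameters for one genotype population.

    DS cells get preferred directions scattered around the four cardinal
    axes (Gaussian jitter), a small independent ON/OFF preferred-direction
    offset, and a concentration drawn from ``kappa_choices``; non-DS cells
    are untuned (κ = 0) with a lower gain.
    """
    rng = np.random.default_rng(seed)
    cells = []
    n_ds = int(round(spec.n_cells * spec.ds_fraction))
    for i in range(spec.n_cells):
        cid = f"{genotype}_{i:04d}" if genotype else f"cell_{i:04d}"
        if i < n_ds:
            cardinal = CARDINALS[int(rng.integers(4))]
            mu_on = (cardinal + rng.normal(0.0, spec.pref_dir_jitter_sd_deg)) % 360.0
            mu_off = (mu_on + rng.normal(0.0, spec.on_off_delta_sd_deg)) % 360.0
            kappa = float(rng.choice(spec.kappa_choices))
            cells.append(
                SyntheticCellParams(
                    cid, is_ds=True, mu_on_deg=mu_on, mu_off_deg=mu_off,
                    kappa_on=kappa, kappa_off=kappa, gain=spec.gain,
                    null_rate=spec.null_rate, off_gain=spec.gain * spec.off_gain_ratio,
                )
            )
        else:
            cells.append(
                SyntheticCellParams(
                    cid, is_ds=False, kappa_on=0.0, kappa_off=0.0,
                    gain=spec.nonds_gain, null_rate=min(spec.null_rate, spec.nonds_gain),
                )
            )
    return SyntheticTruth(cells, protocol, seed=int(rng.integers(2**31)))


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def run_physiology_experiment(cfg: RunConfig, outdir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Generate two genotype populations and run the full physiology pipeline.

    Returns (and optionally writes) the per-cell metrics table, the subtype
    table, and the genotype-comparison report of KS statistics for tuning
    width, strength and Δϕ.
    """
    if not cfg.physiology_genotypes:
        raise ValueError("config names no physiology genotypes")
    protocol = StimulusProtocol(contrasts_pct=tuple(cfg.contrasts_pct), n_trials=cfg.n_trials)
    master = np.random.SeedSequence(cfg.seed)
    geno_seeds = master.spawn(len(cfg.physiology_genotypes))
    gating_contrast = max(protocol.contrasts_pct)

    metric_rows = []
    counts_log = {}
    for (genotype, spec), ss in zip(cfg.physiology_genotypes.items(), geno_seeds):
        truth = build_truth(spec, protocol, int(ss.generate_state(1)[0] % (2**31)), genotype)
        rs = generate_population(truth)
        qc_ok = {}
        for cell in rs.cells:
            times, duration = rs.global_spike_train(cell)
            ok, reason = qc_filter(times, duration)
            qc_ok[cell] = (ok, reason)
        kept = [c for c, (ok, _) in qc_ok.items() if ok]

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dsi = np.array(
                [compute_dsi(compute_tuning_curve(rs, c, gating_contrast)) for c in kept]
            )
            mixture, ds_mask = gate_dsgc(dsi, random_state=cfg.seed)
            ds_cells = [c for c, m in zip(kept, ds_mask) if m]
            oods_labels, splits = isolate_oods(rs, ds_cells)
            for cell in kept:
                tc = compute_tuning_curve(rs, cell, gating_contrast)
                m = compute_metrics(tc)
                is_ds = cell in ds_cells
                is_oods = bool(oods_labels.get(cell, False))
                dphi = splits[cell].delta_phi_deg if (is_oods and cell in splits) else np.nan
                metric_rows.append(
                    dict(
                        cell_id=cell, genotype=genotype, contrast_pct=gating_contrast,
                        dsi=m.dsi, pref_dir_deg=m.pref_dir_deg, width_deg=m.width_deg,
                        strength=m.strength, delta_phi_deg=dphi,
                        is_ds=is_ds, is_oods=is_oods,
                        qc_pass=True, dsi_threshold=mixture.crossing_threshold,
                    )
                )
        counts_log[genotype] = dict(
            n_recorded=len(rs.cells), n_qc_pass=len(kept), n_ds=len(ds_cells),
            n_oods=int(sum(oods_labels.values())),
        )

    metrics = pd.DataFrame(metric_rows)

    # subtype clustering on ooDSGC preferred directions, per genotype
    subtype_rows = []
    for genotype in cfg.physiology_genotypes:
        sel = metrics[(metrics.genotype == genotype) & metrics.is_oods]
        if len(sel) >= 4:
            labels, centers = assign_subtypes(sel.pref_dir_deg.to_numpy())
            for cid, lab in zip(sel.cell_id, labels):
                subtype_rows.append(
                    dict(cell_id=cid, genotype=genotype, subtype=int(lab),
                         subtype_center_deg=float(centers[lab]))
                )
    subtypes = pd.DataFrame(subtype_rows)

    # genotype comparisons (KS) on ooDSGC tuning metrics
    comparison_rows = []
    genos = list(cfg.physiology_genotypes)
    if len(genos) >= 2:
        a, b = genos[0], genos[1]
        for metric in ("width_deg", "strength", "delta_phi_deg"):
            va = metrics[(metrics.genotype == a) & metrics.is_oods][metric].to_numpy()
            vb = metrics[(metrics.genotype == b) & metrics.is_oods][metric].to_numpy()
            va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
            if va.size and vb.size:
                stat, p = compare_populations(va, vb)
                comparison_rows.append(
                    dict(metric=metric, group_a=a, group_b=b, ks_statistic=stat,
                         p_value=p, n_a=len(va), n_b=len(vb))
                )
    report = pd.DataFrame(comparison_rows)

    out = {"metrics": metrics, "subtypes": subtypes, "comparison": report}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            df.to_csv(outdir / f"physiology_{name}.csv", index=False)
        manifest = dict(
            experiment=cfg.name, stage="physiology", seed=cfg.seed,
            package_version=__version__, config=json.loads(json.dumps(asdict(cfg))),
            stage_counts=counts_log,
        )
        (outdir / "physiology_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def run_mosaic_experiment(cfg: RunConfig, outdir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Score synthetic mosaic fields per animal and genotype against the null.

    Each animal contributes ``n_fields`` fields; per-animal mean VDRI and
    density are compared against the mean and the 1st-99th percentile
    envelope of density-matched random (hard-core) arrays.
    """
    if not cfg.mosaic_genotypes:
        raise ValueError("config names no mosaic genotypes")
    bounds = (0.0, 0.0, cfg.field_size_um, cfg.field_size_um)
    master = np.random.SeedSequence((cfg.seed, 1))
    rows = []
    for genotype, spec in cfg.mosaic_genotypes.items():
        for animal in range(cfg.n_animals):
            fields = []
            for fld in range(cfg.n_fields):
                seed = int(master.spawn(1)[0].generate_state(1)[0] % (2**31))
                m = generate_mosaic(
                    spec.process, spec.density_cells_mm2, bounds,
                    d_min_um=spec.d_min_um, jitter_sd_um=spec.jitter_sd_um, seed=seed,
                )
                res = voronoi_domains(m)
                fields.append(res)
                rows.append(
                    dict(genotype=genotype, animal=animal, field=fld, level="field",
                         vdri=res.vdri, density_cells_mm2=res.density_cells_mm2,
                         n_interior=len(res.domain_areas_um2))
                )
            mean_vdri, mean_density = per_animal_summary(fields)
            rows.append(
                dict(genotype=genotype, animal=animal, field=-1, level="animal",
                     vdri=mean_vdri, density_cells_mm2=mean_density,
                     n_interior=int(np.mean([len(f.domain_areas_um2) for f in fields])))
            )
    table = pd.DataFrame(rows)

    mean_density = float(table[table.level == "field"].density_cells_mm2.mean())
    null = random_null(
        mean_density, bounds, n_sims=cfg.null_sims,
        seed=int(np.random.SeedSequence((cfg.seed, 2)).generate_state(1)[0] % (2**31)),
    )
    envelope = pd.DataFrame(
        [dict(null_mean=null.mean, p01=null.percentile(1), p50=null.percentile(50),
              p99=null.percentile(99), n_sims=cfg.null_sims, density_cells_mm2=mean_density)]
    )
    out = {"fields": table, "null_envelope": envelope}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "mosaic_fields.csv", index=False)
        envelope.to_csv(outdir / "mosaic_null_envelope.csv", index=False)
        manifest = dict(
            experiment=cfg.name, stage="mosaic", seed=cfg.seed,
            package_version=__version__, config=json.loads(json.dumps(asdict(cfg))),
        )
        (outdir / "mosaic_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
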
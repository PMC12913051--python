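"""End-to-end synthetic pipeline: simulate -> quantify -> infer.

``PipelineConfig`` gathers the tunable constants of every stage; unknown
keys are rejected up front so a typo in a config file cannot silently
fall back to a default.  A single seed fans out to per-stage substreams
(``numpy.random.SeedSequence.spawn``) so adding or reordering a stage
never perturbs another stage's draws.  Every run writes its fully
resolved configuration next to the outputs, and every output table
carries provenance columns (stage, seed, config hash).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import asl as asl_mod
from . import dimac as dimac_mod
from . import octa as octa_mod
from . import stats as stats_mod
from . import trust as trust_mod
from .io import add_provenance, config_hash, write_image, write_table, write_volume
from .synthetic import (CohortTruth, TreeSpec, default_asl_truth, gen_cohort,
                        gen_dimac_series, gen_retina_image, gen_trust_curve)

__all__ = ["PipelineConfig", "run_pipeline", "results_report"]

logger = logging.getLogger(__name__)


@dataclass
class AslParams:
    t1_blood: float = 1.65
    alpha: float = 0.85
    tau: float = 1.5
    r2_min: float = 0.6
    m0_csf: float = 1000.0
    noise_sd: float = 0.5
    shape: tuple[int, int, int] = (8, 8, 2)


@dataclass
class TrustParams:
    sao2: float = 0.98
    t2_true: float = 0.065
    hb: float = 13.5
    noise_sd: float = 2.0
    hb_coefficients: tuple[float, float] | None = None
    convention: str = "printed"


@dataclass
class DimacParams:
    pi_true: float = 0.30
    heart_period: float = 1.0
    duration: float = 60.0
    noise_sd: float = 3.3
    mean_level: float = 100.0


@dataclass
class OctaParams:
    pixel_pitch: float = 9.375
    image_size: int = 320
    eye: str = "left"


@dataclass
class StatsParams:
    outlier_k: float = 2.5
    slope_oestradiol: float = 0.0195
    slope_resprog: float = 0.17
    n_participants: int = 21


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "cyclovasc_out"
    strict: bool = False
    asl: AslParams = field(default_factory=AslParams)
    trust: TrustParams = field(default_factory=TrustParams)
    dimac: DimacParams = field(default_factory=DimacParams)
    octa: OctaParams = field(default_factory=OctaParams)
    stats: StatsParams = field(default_factory=StatsParams)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build a config from nested dicts, rejecting unknown keys."""

        def build(klass, d, path):
            names = {f.name: f for f in fields(klass)}
            unknown = set(d) - set(names)
            if unknown:
                raise ValueError(
                    f"unknown config key(s) {sorted(unknown)} under {path!r}")
            kwargs = {}
            for key, val in d.items():
                f = names[key]
                if dataclasses.is_dataclass(f.type) or key in (
                        "asl", "trust", "dimac", "octa", "stats"):
                    sub = {"asl": AslParams, "trust": TrustParams,
                           "dimac": DimacParams, "octa": OctaParams,
                           "stats": StatsParams}[key]
                    kwargs[key] = build(sub, val, f"{path}.{key}")
                else:
                    kwargs[key] = val
            return klass(**kwargs)

        return build(cls, data, "pipeline")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> asl -> trust -> dimac -> octa -> stats.

    Returns a dict of the key results and writes CSV/NIfTI/PNG artefacts
    under ``config.out_dir``.  Deterministic for a fixed seed: two runs
    write byte-identical CSVs.
    """
    if config.strict and config.trust.hb_coefficients is None \
            and config.trust.hb is None:
        raise ValueError("strict mode: supply trust.hb or explicit "
                         "trust.hb_coefficients (no silent Hb default)")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = config.to_dict()
    # hash covers the scientific parameters, not where outputs land
    chash = config_hash({k: v for k, v in resolved.items() if k != "out_dir"})
    (out / "resolved_config.json").write_text(
        json.dumps(resolved, indent=2, default=str) + "\n")
    seeds = _stage_seeds(config.seed)
    results: dict = {"config_hash": chash}

    # --- ASL -------------------------------------------------------------
    truth = default_asl_truth(shape=tuple(config.asl.shape),
                              noise_sd=config.asl.noise_sd, seed=seeds[0])
    schedule = asl_mod.PLDSchedule(
        plds=tuple(np.arange(0.25, 3.001, 0.25)), tau=config.asl.tau,
        pairs_per_pld=5)
    from .synthetic import gen_asl_dataset
    series, truth = gen_asl_dataset(truth, schedule)
    # CSF reference chosen so the derived blood M0 matches the generator's
    cal = asl_mod.M0Calibration(m0_csf=1.0)
    cal = asl_mod.M0Calibration(m0_csf=truth.m0_blood / cal.m0_blood)
    fits = asl_mod.fit_kinetic(series, cal, asl_mod.FitConfig(
        t1_blood=config.asl.t1_blood, alpha=config.asl.alpha,
        r2_min=config.asl.r2_min))
    gm_cbf, gm_aat = asl_mod.global_summary(fits)
    write_volume(fits.f, out / "perfusion.nii.gz")
    write_volume(fits.aat, out / "aat.nii.gz")
    write_volume(fits.r2, out / "r2.nii.gz")
    asl_df = pd.DataFrame([{"global_perfusion": gm_cbf, "global_aat": gm_aat,
                            "n_passed": int(fits.passed.sum())}])
    write_table(add_provenance(asl_df, "asl", config.seed, chash),
                out / "asl_summary.csv")
    results.update(global_perfusion=gm_cbf, global_aat=gm_aat)

    # --- TRUST -----------------------------------------------------------
    sample = gen_trust_curve(config.trust.t2_true, s0=100.0,
                             noise_sd=config.trust.noise_sd, seed=seeds[1])
    oxi = trust_mod.oximetry_from_sample(
        sample, gm_cbf=gm_cbf, hb=config.trust.hb, sao2=config.trust.sao2,
        hb_coefficients=config.trust.hb_coefficients,
        convention=config.trust.convention, strict=config.strict)
    oxi_df = pd.DataFrame([dataclasses.asdict(oxi)])
    write_table(add_provenance(oxi_df, "trust", config.seed, chash),
                out / "oximetry.csv")
    results.update(oef=oxi.oef, cmro2=oxi.cmro2, t2_blood=oxi.t2_blood)

    # --- DIMAC (left/right carotids) ---------------------------------------
    pi_rows = []
    for side, seed in (("left", seeds[2]), ("right", seeds[3])):
        series_d, truth_d = gen_dimac_series(
            mean_level=config.dimac.mean_level, pi_true=config.dimac.pi_true,
            heart_period=config.dimac.heart_period,
            duration=config.dimac.duration, noise_sd=config.dimac.noise_sd,
            seed=seed)
        pi, beats = dimac_mod.compute_pi(series_d)
        pi_rows.append({"laterality": side, "pi": pi, "n_beats": len(beats),
                        "pi_true": truth_d.pi_true})
        results[f"pi_{side}"] = pi
    write_table(add_provenance(pd.DataFrame(pi_rows), "dimac", config.seed,
                               chash), out / "pulsatility.csv")

    # --- OCT-A (left/right eyes) -------------------------------------------
    octa_rows = []
    for side, seed in (("left", seeds[4]), ("right", seeds[5])):
        angio, truth_tab = gen_retina_image(
            TreeSpec(), pixel_pitch=config.octa.pixel_pitch,
            image_size=config.octa.image_size, seed=seed)
        write_image(angio.mask, out / f"angiogram_{side}.png")
        cleaned = octa_mod.clean_mask(angio.mask)
        angio_c = octa_mod.BinaryAngiogram(
            mask=cleaned.astype(np.uint8), pixel_pitch=angio.pixel_pitch)
        skel = octa_mod.skeletonize_and_graph(angio_c)
        segments = octa_mod.extract_segments(skel)
        geom = octa_mod.SectorGeometry(center=angio_c.center,
                                       pixel_pitch=angio_c.pixel_pitch,
                                       eye=side)
        metrics = octa_mod.sector_metrics(segments, geom, angio_c)
        metrics["laterality"] = side
        octa_rows.append(metrics)
        results[f"retinal_resistance_{side}"] = metrics["resistance_global"]
        results[f"vessel_density_parafovea_{side}"] = metrics[
            "density_parafovea"]
    write_table(add_provenance(pd.DataFrame(octa_rows), "octa", config.seed,
                               chash), out / "retina_metrics.csv")

    # --- endocrine statistics ---------------------------------------------
    truth_c = CohortTruth(n_participants=config.stats.n_participants,
                          slope_oestradiol=config.stats.slope_oestradiol,
                          slope_resprog=config.stats.slope_resprog,
                          seed=seeds[6])
    panel, outcomes = gen_cohort(truth_c)
    write_table(add_provenance(panel, "simulate", config.seed, chash),
                out / "hormone_panel.csv")
    write_table(add_provenance(outcomes, "simulate", config.seed, chash),
                out / "outcomes.csv")
    merged = outcomes.merge(panel, on=["participant", "phase"])
    lmm = stats_mod.fit_hormone_lmm(merged, truth_c.metric)
    lmm_df = pd.DataFrame([dataclasses.asdict(r) for r in lmm.values()])
    write_table(add_provenance(lmm_df, "stats", config.seed, chash),
                out / "lmm_results.csv")
    for h, r in lmm.items():
        results[f"slope_{h}"] = r.slope
        results[f"chi2_{h}"] = r.chi2
        results[f"p_{h}"] = r.p
    results["n14_check"] = stats_mod.required_sample_size(0.98, 0.90, 0.05)
    return results


def results_report(lmm_csv: str | Path) -> str:
    """Format LMM results as an outcome x hormone x chi2 x p table."""
    df = pd.read_csv(lmm_csv)
    lines = [f"{'Outcome':<24}{'Hormone':<20}{'chi2':>10}{'p':>12}"
             f"{'Direction':>11}"]
    for _, r in df.iterrows():
        direction = ("increase" if (r["p"] < 0.05 and r["slope"] > 0)
                     else "decrease" if (r["p"] < 0.05 and r["slope"] < 0)
                     else "=")
        p_str = "<0.001" if r["p"] < 0.001 else f"{r['p']:.3f}"
        lines.append(f"{r['metric']:<24}{r['hormone']:<20}"
                     f"{r['chi2']:>10.3f}{p_str:>12}{direction:>11}")
    return "\n".join(lines)
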
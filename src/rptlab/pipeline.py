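"""End-to-end pipeline: ingest -> screen -> variables -> fits -> features -> stats.

Stage order follows the analysis protocol: participant screening first,
then the per-category (K, sigma, H) variables, group-level curve fits
(which set the coherence reference for individual fits), individual fits
and admissibility, feature extraction with the feature-level outlier
policy, and finally cohort summaries and — when several cohorts are
present — the nonparametric comparison battery.

Every artifact is written as CSV or JSON under the output directory, with
a run manifest capturing the configuration; identical config and inputs
produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import (DEFAULT_AGE_MIDPOINTS, age_regressions,
                           compare_cohorts, summaries_table)
from .curve_fits import (AdmissibilityPolicy, CurveFit, fit_admissibility,
                         fit_boundary_envelope, fit_logarithmic, fit_powerlaw,
                         fit_quadratic, fit_radial)
from .features import (FEATURE_NAMES, K_EVAL_DEFAULT, OutlierPolicy,
                       extract_features, feature_outlier_filter)
from .ratings_io import (ScreeningPolicy, parse_ratings, retained_records,
                         screen_participants, screening_summary,
                         screening_table)
from .rpt_variables import DenominatorPolicy, summarize_ratings
from .synthetic_data import GeneratorConfig, generate_cohort

log = logging.getLogger("rptlab")

VALUE_FAMILIES = ("powerlaw", "logarithmic")


@dataclass
class PipelineConfig:
    ratings_path: str | None = None
    meta_path: str | None = None
    generator: GeneratorConfig | None = None
    screening: ScreeningPolicy = field(default_factory=ScreeningPolicy)
    admissibility: AdmissibilityPolicy = field(default_factory=AdmissibilityPolicy)
    outliers: OutlierPolicy = field(default_factory=OutlierPolicy)
    denominator: DenominatorPolicy = "all"
    k_eval: float = K_EVAL_DEFAULT
    out_dir: str = "rpt_out"
    seed: int = 0
    make_plots: bool = False


def _xy(df: pd.DataFrame, x: str, y: str) -> list[tuple[float, float]]:
    return list(zip(df[x].abs(), df[y]))


def group_fits(variables: pd.DataFrame) -> dict[tuple[str, str, str], CurveFit]:
    """Pooled fits per (cohort, valence, family) over participant x category points.

    Value-function fits use (|K|, H); limit-function fits use (|K|, sigma);
    the trade-off fit is radial on the per-participant-category (H-, H+)
    pairs. Avoidance is fitted in magnitude space.
    """
    fits: dict[tuple[str, str, str], CurveFit] = {}
    for (cohort, valence), grp in variables.groupby(["cohort", "valence"],
                                                    observed=True):
        fits[(cohort, valence, "powerlaw")] = fit_powerlaw(_xy(grp, "K", "H"))
        fits[(cohort, valence, "logarithmic")] = fit_logarithmic(_xy(grp, "K", "H"))
        fits[(cohort, valence, "quadratic")] = fit_quadratic(_xy(grp, "K", "sigma"))
    for cohort, grp in variables.groupby("cohort", observed=True):
        piv = tradeoff_points(grp)
        pts = piv[["H_minus", "H_plus"]].to_numpy()
        fits[(cohort, "joint", "radial")] = fit_radial(pts)
    return fits


def tradeoff_points(variables: pd.DataFrame) -> pd.DataFrame:
    """(H-, H+) per participant x category, from the long variable table."""
    piv = variables.pivot_table(index=["participant_id", "category"],
                                columns="valence", values="H",
                                observed=True).reset_index()
    piv = piv.rename(columns={"avoidance": "H_minus", "approach": "H_plus"})
    for col in ("H_minus", "H_plus"):
        if col not in piv.columns:
            piv[col] = 0.0
    return piv


def individual_fits(
    variables: pd.DataFrame,
    group: dict[tuple[str, str, str], CurveFit],
    policy: AdmissibilityPolicy,
) -> tuple[dict[tuple[str, str, str], CurveFit], pd.DataFrame]:
    """Per-participant fits with admissibility against the group reference."""
    fits: dict[tuple[str, str, str], CurveFit] = {}
    rows = []
    for (pid, cohort, valence), grp in variables.groupby(
            ["participant_id", "cohort", "valence"], observed=True):
        for family, fitter, pts in (
            ("powerlaw", fit_powerlaw, _xy(grp, "K", "H")),
            ("logarithmic", fit_logarithmic, _xy(grp, "K", "H")),
            ("quadratic", fit_quadratic, _xy(grp, "K", "sigma")),
        ):
            fit = fitter(pts)
            ref = group.get((cohort, valence, family))
            decision = fit_admissibility(fit, pts, ref, policy)
            if not decision.admissible:
                fit = dataclasses.replace(fit, valid=False)
            fits[(str(pid), valence, family)] = fit
            rows.append({
                "participant_id": pid, "cohort": cohort, "valence": valence,
                "family": family, "params": list(np.round(fit.params, 10)),
                "R2": fit.quality.r2, "R2_adj": fit.quality.r2_adj,
                "F": fit.quality.f_statistic, "p": fit.quality.p_value,
                "n_points": fit.n_points, "admissible": decision.admissible,
                "reasons": ";".join(decision.reasons),
            })
    return fits, pd.DataFrame(rows)


def participant_features(
    variables: pd.DataFrame,
    fits: dict[tuple[str, str, str], CurveFit],
    k_eval: float = K_EVAL_DEFAULT,
) -> pd.DataFrame:
    """15-feature table, one row per participant."""
    piv = tradeoff_points(variables)
    cohorts = variables.drop_duplicates("participant_id").set_index(
        "participant_id")["cohort"]
    rows = []
    for pid, grp in piv.groupby("participant_id", observed=True):
        pid = str(pid)
        fv = extract_features(
            pid,
            fits.get((pid, "approach", "powerlaw")),
            fits.get((pid, "avoidance", "powerlaw")),
            fits.get((pid, "approach", "logarithmic")),
            fits.get((pid, "avoidance", "logarithmic")),
            fits.get((pid, "approach", "quadratic")),
            fits.get((pid, "avoidance", "quadratic")),
            grp[["H_minus", "H_plus"]].to_numpy(),
            k_eval=k_eval,
        )
        row = {"participant_id": pid, "cohort": cohorts.get(pid, "default")}
        row.update(fv.as_dict())
        del row["participant_id"]
        row["participant_id"] = pid
        rows.append(row)
    return pd.DataFrame(rows, columns=["participant_id", "cohort", *FEATURE_NAMES])


def _fit_record(key, fit: CurveFit, level: str) -> dict:
    cohort, valence, family = key if level == "group" else (None, key[1], key[2])
    return {
        "level": level, "cohort": cohort, "valence": valence, "family": family,
        "params": [None if not np.isfinite(p) else float(p) for p in fit.params],
        "R2": None if not np.isfinite(fit.quality.r2) else fit.quality.r2,
        "n_points": fit.n_points, "valid": fit.valid,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- ingest -----------------------------------------------------------
    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=config.generator.seed
                                  if config.generator.seed else config.seed)
        cohort = generate_cohort(gen)
        records, meta = cohort.records, cohort.meta
        log.info("simulated cohort: %d participants", gen.n_participants)
    elif config.ratings_path is not None:
        parsed = parse_ratings(config.ratings_path)
        records = parsed.records
        incomplete = parsed.completeness[~parsed.completeness["complete"]]
        if len(incomplete):
            log.warning("%d incomplete participant x category groups", len(incomplete))
        meta = (pd.read_csv(config.meta_path)
                if config.meta_path else None)
    else:
        raise ValueError("config needs either ratings_path or generator")
    records.to_csv(out / "ratings.csv", index=False)

    # --- screening --------------------------------------------------------
    reports = screen_participants(records, meta, config.screening)
    screening_table(reports).to_csv(out / "screening.csv", index=False)
    summary = screening_summary(reports)
    (out / "screening_summary.json").write_text(json.dumps(summary, indent=2))
    records = retained_records(records, reports)
    log.info("screening: %d retained / %d excluded",
             summary["n_retained"], summary["n_excluded"])
    if records.empty:
        raise ValueError("no participants retained after screening")

    # --- variables --------------------------------------------------------
    variables = summarize_ratings(records, denominator=config.denominator)
    variables.to_csv(out / "variables.csv", index=False)

    # --- fits -------------------------------------------------------------
    gfits = group_fits(variables)
    ifits, fit_table = individual_fits(variables, gfits, config.admissibility)
    fit_records = [_fit_record(k, f, "group") for k, f in gfits.items()]
    (out / "group_fits.json").write_text(json.dumps(fit_records, indent=2))
    fit_table.to_csv(out / "individual_fits.csv", index=False)

    envelopes = []
    for (cohort, valence), grp in variables.groupby(["cohort", "valence"],
                                                    observed=True):
        for family, xy in (("powerlaw", _xy(grp, "K", "H")),
                           ("logarithmic", _xy(grp, "K", "H")),
                           ("quadratic", _xy(grp, "K", "sigma"))):
            try:
                env = fit_boundary_envelope(xy, family)
            except ValueError:
                continue
            envelopes.append({"cohort": cohort, "valence": valence,
                              "family": family, "params": list(env.params),
                              "containment": env.containment})
    (out / "envelopes.json").write_text(json.dumps(envelopes, indent=2))

    # --- features ---------------------------------------------------------
    feats = participant_features(variables, ifits, k_eval=config.k_eval)
    retained, exclusion_log = feature_outlier_filter(feats, config.outliers)
    feats.to_csv(out / "features_raw.csv", index=False)
    retained.to_csv(out / "features.csv", index=False)
    exclusion_log.to_csv(out / "feature_exclusions.csv", index=False)

    # --- cohort statistics ------------------------------------------------
    summaries = summaries_table(retained)
    summaries.to_csv(out / "feature_summaries.csv", index=False)
    n_cohorts = retained["cohort"].nunique()
    if n_cohorts >= 2:
        comparison = compare_cohorts(retained)
        comparison.to_csv(out / "cohort_comparison.csv", index=False)
    if meta is not None and "age_group" in meta.columns:
        ages = meta.set_index(meta["participant_id"].astype(str))["age_group"].map(
            DEFAULT_AGE_MIDPOINTS)
        ages = ages[np.isfinite(ages)]
        if len(set(ages.reindex(retained["participant_id"].astype(str)).dropna())) > 1 \
                and len(retained) >= 10:
            regs = age_regressions(retained, ages)
            pd.DataFrame([r.__dict__ for r in regs]).to_csv(
                out / "age_regressions.csv", index=False)

    if config.make_plots:
        from .cohort_stats import violin_plots
        violin_plots(retained, out / "feature_violins.png")

    manifest = {
        "rptlab_version": __version__,
        "seed": config.seed,
        "config": _manifest_config(config),
        "n_participants_in": summary["n_participants"],
        "n_retained": summary["n_retained"],
        "n_feature_excluded": len(exclusion_log),
        "n_cohorts": int(n_cohorts),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _manifest_config(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj
    return enc(config)
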
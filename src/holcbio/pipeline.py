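"""End-to-end orchestration: simulate → ingest → accumulate → alpha → beta → report.

A single JSON config drives the run; every stage derives its own seed from
the master seed (hash of master seed and stage name), writes its outputs
before the next stage starts, and is recorded in a manifest with seeds and
row counts. Reruns of the same config are numerically identical, and
changing one stage's seed leaves upstream stages untouched.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _VERSION
from . import accumulation, alpha, beta, ingest, synthetic
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "ingest", "accumulate", "alpha", "beta", "report")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed, isolated across stages."""
    digest = hashlib.blake2b(
        f"{master_seed}:{stage}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


@dataclass
class RunConfig:
    outdir: str = "holcbio_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    window: tuple[str, str] = synthetic.DEFAULT_WINDOW
    min_per_cell: int = 5
    mcmc_profile: str = "test"  # "test" or "paper"
    n_perm: int = 999
    subset: str = "all"
    region: synthetic.RegionConfig = field(default_factory=synthetic.RegionConfig)
    community: synthetic.CommunityConfig = field(
        default_factory=synthetic.CommunityConfig
    )
    truth: synthetic.TruthParams | None = None
    paths: dict = field(default_factory=dict)  # external inputs when not simulating

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}")
        if self.mcmc_profile not in ("test", "paper"):
            raise ConfigurationError("mcmc_profile must be 'test' or 'paper'")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = json.load(fh)
        kwargs = dict(doc)
        if "region" in kwargs:
            kwargs["region"] = synthetic.RegionConfig(**kwargs["region"])
        if "community" in kwargs:
            kwargs["community"] = synthetic.CommunityConfig(**kwargs["community"])
        if "truth" in kwargs and kwargs["truth"] is not None:
            kwargs["truth"] = synthetic.TruthParams(**kwargs["truth"])
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        if "window" in kwargs:
            kwargs["window"] = tuple(kwargs["window"])
        return cls(**kwargs)

    def input_path(self, key: str) -> Path:
        defaults = {
            "geojson": "region.geojson",
            "records": "records.csv",
            "grid": "impervious.asc",
        }
        if key in self.paths:
            return Path(self.paths[key])
        return Path(self.outdir) / defaults[key]


def _validate(config: RunConfig) -> None:
    if "ingest" in config.stages and "simulate" not in config.stages:
        for key in ("geojson", "records", "grid"):
            p = config.input_path(key)
            if not p.exists():
                raise ConfigurationError(f"required input {key} not found at {p}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages in order; return (and write) the manifest."""
    _validate(config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": _VERSION,
        "master_seed": config.seed,
        "outdir": str(out),
        "stages": {},
    }

    def record(stage: str, seed: int | None, outputs: list[str], rows: dict):
        manifest["stages"][stage] = {
            "seed": seed,
            "outputs": outputs,
            "rows": {k: int(v) for k, v in rows.items()},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    try:
        if "simulate" in config.stages:
            _stage_simulate(config, out, record)
        if "ingest" in config.stages:
            _stage_ingest(config, out, record)
        if "accumulate" in config.stages:
            _stage_accumulate(config, out, record)
        if "alpha" in config.stages:
            _stage_alpha(config, out, record)
        if "beta" in config.stages:
            _stage_beta(config, out, record)
        if "report" in config.stages:
            text = render_report(out)
            (out / "report.txt").write_text(text)
            record("report", None, ["report.txt"], {})
    except Exception as exc:
        manifest["failed_stage"] = _current_stage(manifest)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise RuntimeError(
            f"pipeline aborted after stage {_current_stage(manifest)!r}: {exc}"
        ) from exc
    return manifest


def _current_stage(manifest: dict) -> str:
    done = list(manifest["stages"])
    for s in STAGES:
        if s not in done:
            return s
    return "report"


def _stage_simulate(config: RunConfig, out: Path, record) -> None:
    seed = stage_seed(config.seed, "simulate")
    region = synthetic.make_region(config.region, seed)
    records = synthetic.simulate_observation_records(
        region, config.community, stage_seed(config.seed, "records"),
        window=config.window,
    )
    synthetic.write_region_geojson(region, out / "region.geojson")
    synthetic.write_impervious_grid(region, out / "impervious.asc")
    synthetic.write_records_csv(records, out / "records.csv", seed=seed)
    truth = config.truth or synthetic.TruthParams()
    synthetic.write_truth(truth, out / "truth.json", seed=seed)
    record(
        "simulate", seed,
        ["region.geojson", "impervious.asc", "records.csv", "truth.json"],
        {"neighborhoods": len(region.neighborhoods), "records": len(records)},
    )


def _stage_ingest(config: RunConfig, out: Path, record) -> None:
    nb, report = ingest.read_holc_geojson(config.input_path("geojson"))
    grid = ingest.read_esri_ascii(config.input_path("grid"))
    nb = ingest.attach_impervious(nb, grid)
    recs, report2 = ingest.read_observations_csv(config.input_path("records"))
    report.steps.extend(report2.steps)

    w0 = date.fromisoformat(str(config.window[0]))
    w1 = date.fromisoformat(str(config.window[1]))
    recs, report = ingest.filter_records(recs, w0, w1, report)
    recs, _, report = ingest.assign_points_to_polygons(recs, nb, report)
    _, recs, report = ingest.city_clade_inclusion(
        recs, nb, config.min_per_cell, report
    )
    richness, report = ingest.richness_table(recs, nb, config.subset, report)

    nb_out = nb.drop(columns=["geometry"])
    nb_out.to_csv(out / "neighborhoods.csv", index=False)
    recs.to_csv(out / "records_assigned.csv", index=False)
    richness.to_csv(out / "richness.csv", index=False)
    report.write_json(out / "filter_report.json")
    record(
        "ingest", None,
        ["neighborhoods.csv", "records_assigned.csv", "richness.csv",
         "filter_report.json"],
        {"neighborhoods": len(nb), "records": len(recs), "modeled": len(richness)},
    )


def _stage_accumulate(config: RunConfig, out: Path, record) -> None:
    recs = pd.read_csv(out / "records_assigned.csv", parse_dates=["observed_on"])
    nb = pd.read_csv(out / "neighborhoods.csv")
    curves = accumulation.curves_by(recs, nb, by=("holc_grade",))
    pd.concat([c.to_frame() for c in curves.values()]).to_csv(
        out / "accumulation_curves.csv", index=False
    )
    comp = accumulation.compare_to_reference(curves, reference="A")
    comp.to_csv(out / "accumulation_comparison.csv", index=False)
    record(
        "accumulate", None,
        ["accumulation_curves.csv", "accumulation_comparison.csv"],
        {"strata": len(curves)},
    )


def _stage_alpha(config: RunConfig, out: Path, record) -> None:
    seed = stage_seed(config.seed, "alpha")
    richness = pd.read_csv(out / "richness.csv")
    data = alpha.build_model_data(richness)
    mcmc = (
        alpha.McmcConfig.paper_profile(seed)
        if config.mcmc_profile == "paper"
        else alpha.McmcConfig.test_profile(seed)
    )
    samples = alpha.sample_posterior(data, alpha.PriorConfig(), mcmc)
    conv = alpha.convergence_report(samples)
    logger.info("alpha stage: max R-hat %.4f", max(conv.rhat.values()))
    samples.to_frame().to_csv(out / "posterior_draws.csv", index=False)
    with open(out / "convergence.json", "w") as fh:
        json.dump(conv.to_dict(), fh, indent=2)
    summary = pd.concat(
        [
            alpha.summarize_grades(samples, data, level="overall", seed=seed),
            alpha.summarize_grades(samples, data, level="city"),
        ]
    )
    summary.to_csv(out / "grade_summary.csv", index=False)
    contrasts = pd.concat(
        [
            alpha.grade_contrasts(samples, data, level="overall", seed=seed),
            alpha.grade_contrasts(samples, data, level="city"),
        ]
    )
    contrasts.to_csv(out / "contrasts.csv", index=False)
    record(
        "alpha", seed,
        ["posterior_draws.csv", "convergence.json", "grade_summary.csv",
         "contrasts.csv"],
        {"neighborhoods": data.n, "draws": samples.theta.shape[0] * samples.theta.shape[1]},
    )


def _stage_beta(config: RunConfig, out: Path, record) -> None:
    seed = stage_seed(config.seed, "beta")
    recs = pd.read_csv(out / "records_assigned.csv")
    nb = pd.read_csv(out / "neighborhoods.csv")
    matrix, _ = beta.build_presence_matrix(recs, nb, subset=config.subset)
    dist = beta.jaccard_matrix(matrix)
    dist.to_csv(out / "jaccard_distance.csv")
    meta = nb.set_index("neighborhood_id").loc[dist.index]
    overall = beta.permanova(
        dist, meta.reset_index(), terms=("city", "holc_grade"),
        n_perm=config.n_perm, seed=seed,
    )
    overall.table.to_csv(out / "permanova.csv", index=False)
    pairwise = beta.pairwise_permanova(dist, nb, n_perm=config.n_perm, seed=seed)
    pairwise.to_csv(out / "pairwise_permanova.csv", index=False)
    record(
        "beta", seed,
        ["jaccard_distance.csv", "permanova.csv", "pairwise_permanova.csv"],
        {"neighborhoods": len(dist), "pairwise_tests": len(pairwise)},
    )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def _fmt_ci(row) -> str:
    return f"{row['mean_richness']:.2f} ({row['lower']:.2f}, {row['upper']:.2f})"


def render_report(outdir) -> str:
    """Human-readable summary of a completed (or partial) run."""
    out = Path(outdir)
    lines = [f"holcbio {_VERSION} analysis report", "=" * 40, ""]
    grade_order = {g: i for i, g in enumerate(ingest.GRADES)}

    lines.append("Accumulated species richness (reference: grade A)")
    path = out / "accumulation_comparison.csv"
    if path.exists():
        comp = pd.read_csv(path)
        comp = comp.sort_values("stratum", key=lambda s: s.map(grade_order))
        for r in comp.itertuples():
            reached = (
                f"obs to reach {int(r.S_star)}: {int(r.obs_to_reach)}"
                f" (delta = {int(r.delta)})"
                if r.reached
                else f"never reaches {int(r.S_star)}"
            )
            lines.append(f"  grade {r.stratum}: {reached}")
    else:
        lines.append("  [not run]")
    lines.append("")

    lines.append("Model-predicted species richness by grade, median (95% CI)")
    path = out / "grade_summary.csv"
    if path.exists():
        summ = pd.read_csv(path)
        for city in sorted(summ["city"].unique(), key=lambda c: (c != "ALL", c)):
            sub = summ[summ["city"] == city].sort_values(
                "holc_grade", key=lambda s: s.map(grade_order)
            )
            for r in sub.itertuples():
                lines.append(
                    f"  {city:>12s}  {r.holc_grade}: "
                    f"{r.mean_richness:.2f} ({r.lower:.2f}, {r.upper:.2f})"
                )
    else:
        lines.append("  [not run]")
    lines.append("")

    lines.append("Grade contrasts, median difference (95% CI)")
    path = out / "contrasts.csv"
    if path.exists():
        con = pd.read_csv(path)
        for r in con.itertuples():
            sig = " *" if r.significant else ""
            lines.append(
                f"  {r.city:>12s}  {r.pair}: {r.median:.2f} "
                f"({r.lower:.2f}, {r.upper:.2f}){sig}"
            )
    else:
        lines.append("  [not run]")
    lines.append("")

    lines.append("PERMANOVA on Jaccard dissimilarity (sequential terms)")
    path = out / "permanova.csv"
    if path.exists():
        tab = pd.read_csv(path)
        for r in tab.itertuples():
            f_str = f"{r.F:.4f}" if np.isfinite(r.F) else "-"
            p_str = f"{r.p:.4f}" if np.isfinite(r.p) else "-"
            lines.append(
                f"  {r.term:>12s}: df={r.df} SS={r.SS:.4f} R2={r.R2:.4f} "
                f"F={f_str} p={p_str}"
            )
    else:
        lines.append("  [not run]")
    lines.append("")

    lines.append("Pairwise grade PERMANOVA (BH-adjusted within city)")
    path = out / "pairwise_permanova.csv"
    if path.exists():
        tab = pd.read_csv(path)
        for r in tab.itertuples():
            if not r.testable:
                lines.append(f"  {r.city} {r.pair}: untestable")
            else:
                stars = r.stars if isinstance(r.stars, str) else ""
                lines.append(
                    f"  {r.city} {r.pair}: F={r.F:.3f} p={r.p:.4f} "
                    f"p_adj={r.p_adjusted:.4f} {stars}"
                )
    else:
        lines.append("  [not run]")
    lines.append("")
    return "\n".join(lines)
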
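"""End-to-end orchestration: simulate → preprocess → extract → metrics →
stats → report, with a flat key = value config file, named seed streams and
a run manifest for reproducibility.

The analysis follows the session design: a pooled one-way ANOVA (with Tukey
HSD post-hoc) compares the theta/beta ratio across resting state, picking
and coordination on the six frontal/prefrontal electrodes; a RANSAC-robust
first-order regression relates per-game mean TBR (channel F4) to the game's
coordination index; a plain linear fit relates per-subject mean TBR to
individual coordination ability; and a quadratic fit relates response time
to per-trial TBR.
"""

from __future__ import annotations

import argparse
import configparser
import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import (
    CONDITIONS,
    COORDINATION,
    FRONTAL_CHANNELS,
    InputError,
    PICKING,
    RawRecording,
    REGRESSION_CHANNEL,
    REST,
    ChoiceTable,
)
from .coordmetrics import CoordinationScores, ci_table, load_choices, round_ci, save_scores
from .robuststats import (
    AnovaResult,
    RansacConfig,
    RegressionResult,
    TukeyResult,
    fit_polynomial,
    one_way_anova,
    ransac_line,
    tukey_hsd,
)
from .sigproc import load_epochs, load_recording, preprocess, save_epochs
from .synthgen import (
    GeneratorConfig,
    _stream,
    generate_choices,
    generate_recording,
    inject_artifacts,
    save_choices,
    save_recording,
)
from .tbr import aggregate_tbr, band_power_table

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "extract-tbr", "metrics", "stats", "report")

_FLOAT_FMT = "%.10g"  # fixed CSV dialect: comma, '.' decimal, UTF-8, header


@dataclass
class PipelineConfig:
    """Generator settings plus the few analysis-level knobs."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    channel: str = REGRESSION_CHANNEL  # electrode carrying the regressions
    alpha: float = 0.05
    ransac_iterations: int = 2000
    run_ica: bool = True

    def config_hash(self) -> str:
        payload = repr(_asdict_plain(self)).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _asdict_plain(obj):
    d = dataclasses.asdict(obj)

    def conv(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    return conv(d)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Parse a flat ``key = value`` config file with per-module sections.

    Recognised sections: ``[generator]`` (scalar GeneratorConfig fields plus
    ``theta_amp_rest/picking/coordination`` and beta equivalents) and
    ``[analysis]`` (``channel``, ``alpha``, ``ransac_iterations``,
    ``run_ica``).  Missing keys keep their defaults; the file fully
    determines a run given a seed.
    """
    cfg = PipelineConfig()
    if path is None:
        return cfg
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise InputError(f"config file {path} not found or unreadable")
    gen = cfg.generator
    if parser.has_section("generator"):
        for key, raw in parser.items("generator"):
            if key.startswith(("theta_amp_", "beta_amp_")):
                band, _, cond = key.partition("_amp_")
                if cond not in CONDITIONS:
                    raise InputError(f"unknown condition in config key {key!r}")
                target = gen.condition_theta_amp if band == "theta" else gen.condition_beta_amp
                target[cond] = float(raw)
            elif hasattr(gen, key):
                current = getattr(gen, key)
                if isinstance(current, bool):
                    setattr(gen, key, parser.getboolean("generator", key))
                elif isinstance(current, int):
                    setattr(gen, key, int(raw))
                elif isinstance(current, float):
                    setattr(gen, key, float(raw))
                else:
                    raise InputError(f"config key {key!r} is not a scalar field")
            else:
                raise InputError(f"unknown generator config key {key!r}")
    if parser.has_section("analysis"):
        for key, raw in parser.items("analysis"):
            if key == "channel":
                cfg.channel = raw.strip()
            elif key == "alpha":
                cfg.alpha = float(raw)
            elif key == "ransac_iterations":
                cfg.ransac_iterations = int(raw)
            elif key == "run_ica":
                cfg.run_ica = parser.getboolean("analysis", key)
            else:
                raise InputError(f"unknown analysis config key {key!r}")
    gen.validate()
    return cfg


# ---------------------------------------------------------------------------
# In-memory pipeline
# ---------------------------------------------------------------------------

@dataclass
class SimulatedSession:
    recordings: list[RawRecording]
    choices_picking: ChoiceTable
    choices_coordination: ChoiceTable


@dataclass
class AnalysisResult:
    band: pd.DataFrame
    quantiles: pd.DataFrame
    anova: AnovaResult
    tukey: TukeyResult
    scores: CoordinationScores
    game_table: pd.DataFrame  # game, ci, tbr_mean, inlier
    subject_table: pd.DataFrame  # subject, ica, tbr_mean
    trial_table: pd.DataFrame  # subject, condition, game, tbr, response_time
    reg_ci_tbr: RegressionResult
    reg_ica_tbr: RegressionResult
    reg_rt_quad: RegressionResult
    reg_rt_linear: RegressionResult


def simulate(config: PipelineConfig) -> SimulatedSession:
    """Generate all recordings (with artifacts injected) and choice tables."""
    gen = config.generator
    gen.validate()
    recordings = []
    for s in range(gen.n_subjects):
        rec = generate_recording(gen, s)
        recordings.append(inject_artifacts(rec, gen))
    return SimulatedSession(
        recordings=recordings,
        choices_picking=generate_choices(gen, PICKING),
        choices_coordination=generate_choices(gen, COORDINATION),
    )


def extract_band_powers(
    recordings: list[RawRecording], config: PipelineConfig
) -> pd.DataFrame:
    """Preprocess every recording and stack the per-epoch band-power tables."""
    frames = []
    seed = config.generator.seed
    for rec in recordings:
        subject = rec.subject if rec.subject is not None else 0
        ica_seed = int(_stream(seed, "ica", subject).integers(2**31))
        epochs, _ = preprocess(rec, run_ica=config.run_ica, ica_seed=ica_seed)
        frames.append(band_power_table(epochs))
    return pd.concat(frames, ignore_index=True)


def analyze(
    band: pd.DataFrame,
    choices_coordination: ChoiceTable,
    config: PipelineConfig,
) -> AnalysisResult:
    """Run the full inferential stage on extracted band powers and choices."""
    quantiles = aggregate_tbr(band, by=("condition",), channels=FRONTAL_CHANNELS)

    frontal = band[band["channel"].isin(FRONTAL_CHANNELS)]
    finite = frontal[np.isfinite(frontal["tbr"].astype(float))]
    anova = one_way_anova(finite["tbr"].to_numpy(), finite["condition"].to_numpy())
    tukey = tukey_hsd(finite["tbr"].to_numpy(), finite["condition"].to_numpy(),
                      alpha=config.alpha)

    scores = ci_table(choices_coordination)

    chan = band[band["channel"] == config.channel]
    if chan.empty:
        raise InputError(f"regression channel {config.channel!r} not present")
    coord = chan[(chan["condition"] == COORDINATION) & np.isfinite(chan["tbr"].astype(float))]

    # per-game CI -> mean TBR, RANSAC-robust line
    per_game = coord.groupby("game")["tbr"].mean()
    game_table = pd.DataFrame(
        {"game": per_game.index.astype(int), "ci": scores.ci.loc[per_game.index.astype(int)].to_numpy(),
         "tbr_mean": per_game.to_numpy()}
    ).reset_index(drop=True)
    ransac_seed = int(_stream(config.generator.seed, "ransac").integers(2**31))
    mask = ransac_line(
        game_table["ci"].to_numpy(), game_table["tbr_mean"].to_numpy(),
        RansacConfig(n_iterations=config.ransac_iterations, seed=ransac_seed),
    )
    game_table["inlier"] = mask
    reg_ci = fit_polynomial(
        game_table["ci"].to_numpy(), game_table["tbr_mean"].to_numpy(),
        degree=1, inlier_mask=mask,
    )

    # per-subject iCA -> mean TBR, plain line
    per_subj = coord.groupby("subject")["tbr"].mean()
    subject_table = pd.DataFrame(
        {"subject": per_subj.index.astype(int),
         "ica": scores.ica.loc[per_subj.index.astype(int)].to_numpy(),
         "tbr_mean": per_subj.to_numpy()}
    ).reset_index(drop=True)
    reg_ica = fit_polynomial(
        subject_table["ica"].to_numpy(), subject_table["tbr_mean"].to_numpy(), degree=1
    )

    # per-trial response time vs TBR (both game conditions), quadratic + linear
    trials = chan[chan["condition"].isin((PICKING, COORDINATION))]
    trials = trials[np.isfinite(trials["tbr"].astype(float)) & trials["response_time"].notna()]
    trial_table = trials[["subject", "condition", "game", "tbr", "response_time"]].reset_index(drop=True)
    reg_rt_quad = fit_polynomial(
        trial_table["tbr"].to_numpy(), trial_table["response_time"].to_numpy(), degree=2
    )
    reg_rt_linear = fit_polynomial(
        trial_table["tbr"].to_numpy(), trial_table["response_time"].to_numpy(), degree=1
    )

    return AnalysisResult(
        band=band, quantiles=quantiles, anova=anova, tukey=tukey, scores=scores,
        game_table=game_table, subject_table=subject_table, trial_table=trial_table,
        reg_ci_tbr=reg_ci, reg_ica_tbr=reg_ica, reg_rt_quad=reg_rt_quad,
        reg_rt_linear=reg_rt_linear,
    )


def simulate_and_analyze(config: PipelineConfig) -> AnalysisResult:
    """Convenience: full in-memory run without file output."""
    session = simulate(config)
    band = extract_band_powers(session.recordings, config)
    return analyze(band, session.choices_coordination, config)


# ---------------------------------------------------------------------------
# Manifest, report, file-based run
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, outputs: list[tuple[Path, int]]) -> None:
        self.stages.append(
            {"name": name,
             "outputs": [{"path": str(p), "rows": int(r)} for p, r in outputs]}
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    def save(self, path: Path) -> None:
        Path(path).write_text(self.to_json())


def validate_manifest(manifest: RunManifest, base: Path | None = None) -> None:
    """Check every listed output exists with the recorded row count."""
    for stage in manifest.stages:
        for out in stage["outputs"]:
            p = Path(out["path"])
            if base is not None and not p.is_absolute():
                p = base / p
            if not p.exists():
                raise InputError(f"manifest output missing: {p}")
            if p.suffix == ".csv":
                rows = sum(1 for _ in open(p)) - 1  # minus header
                if rows != out["rows"]:
                    raise InputError(
                        f"row count mismatch for {p}: manifest {out['rows']}, file {rows}"
                    )


def _csv_rows(path: Path) -> int:
    return sum(1 for _ in open(path)) - 1


def _write_csv(frame: pd.DataFrame, path: Path, index: bool = False) -> tuple[Path, int]:
    frame.to_csv(path, index=index, float_format=_FLOAT_FMT)
    return path, len(frame)


def _regression_row(name: str, reg: RegressionResult) -> dict:
    return {
        "model": name,
        "coefficients": [float(c) for c in reg.coefficients],
        "stderr": [float(s) for s in reg.stderr],
        "r_squared": reg.r_squared,
        "f_stat": reg.f_stat,
        "p": reg.p,
        "var_error": reg.var_error,
        "n_inliers": reg.n_inliers,
        "degree": reg.degree,
    }


def write_results(result: AnalysisResult, out_dir: Path, config: PipelineConfig,
                  manifest: RunManifest) -> None:
    """Write the stats-stage CSVs, the summary JSON and the figure."""
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = []
    outputs.append(_write_csv(result.quantiles, out_dir / "quantiles.csv"))
    anova_df = pd.DataFrame(
        [{
            "f_stat": result.anova.f_stat, "df_between": result.anova.df_between,
            "df_within": result.anova.df_within, "p": result.anova.p,
            **{f"mean_{k}": v for k, v in result.anova.group_means.items()},
        }]
    )
    outputs.append(_write_csv(anova_df, out_dir / "anova.csv"))
    outputs.append(_write_csv(result.tukey.pairs, out_dir / "tukey.csv"))
    outputs.append(_write_csv(result.game_table, out_dir / "regression_ci_tbr.csv"))
    outputs.append(_write_csv(result.subject_table, out_dir / "regression_ica_tbr.csv"))
    outputs.append(_write_csv(result.trial_table, out_dir / "regression_rt.csv"))

    summary = {
        "seed": config.generator.seed,
        "config_hash": config.config_hash(),
        "config": _asdict_plain(config),
        "version": __version__,
        "anova": {
            "f_stat": result.anova.f_stat, "df": [result.anova.df_between, result.anova.df_within],
            "p": result.anova.p, "group_means": result.anova.group_means,
        },
        "hardest_games": list(result.scores.hardest_games),
        "min_ci": float(result.scores.ci.min()),
        "regressions": [
            _regression_row("tbr_on_ci", result.reg_ci_tbr),
            _regression_row("tbr_on_ica", result.reg_ica_tbr),
            _regression_row("rt_on_tbr_quadratic", result.reg_rt_quad),
            _regression_row("rt_on_tbr_linear", result.reg_rt_linear),
        ],
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    outputs.append((out_dir / "summary.json", 0))
    manifest.add_stage("stats", outputs)


def plot_ci_tbr(result: AnalysisResult, path: Path) -> Path:
    """Scatter of per-game CI vs mean TBR with the robust line and outliers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gt = result.game_table
    fig, ax = plt.subplots(figsize=(6, 4))
    inl = gt[gt["inlier"]]
    out = gt[~gt["inlier"]]
    ax.scatter(inl["ci"], inl["tbr_mean"], label="inliers", color="tab:blue")
    if len(out):
        ax.scatter(out["ci"], out["tbr_mean"], marker="x", color="tab:red",
                   label="RANSAC outliers")
    xs = np.linspace(gt["ci"].min(), gt["ci"].max(), 50)
    c = result.reg_ci_tbr.coefficients
    ax.plot(xs, c[0] + c[1] * xs, color="k",
            label=result.reg_ci_tbr.equation("CI", "TBR"))
    ax.set_xlabel("coordination index (CI)")
    ax.set_ylabel(f"mean TBR")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def report_text(result: AnalysisResult, config: PipelineConfig) -> str:
    """Human-readable summary of one complete run."""
    lines = ["tacitload run summary", "=" * 21, ""]
    lines.append("TBR distribution by condition (frontal electrodes):")
    lines.append(result.quantiles.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    lines.append("")
    lines.append(f"One-way ANOVA over conditions: {result.anova}")
    lines.append("Tukey HSD pairwise comparisons:")
    lines.append(result.tukey.pairs.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    lines.append("")
    ci_rounded = result.scores.ci.map(round_ci)
    lines.append("Coordination index per game:")
    lines.append(ci_rounded.to_frame().T.to_string())
    hardest = ", ".join(f"#{g}" for g in result.scores.hardest_games)
    lines.append(
        f"Most difficult game(s): {hardest} "
        f"(CI = {round_ci(float(result.scores.ci.min())):.3f})"
    )
    lines.append("")
    n = len(result.game_table)
    k = result.reg_ci_tbr.n_inliers
    lines.append(
        f"RANSAC inliers: {k}/{n} games = {100.0 * k / n:.0f}% of the data"
    )
    lines.append(f"TBR-on-CI (inliers): {result.reg_ci_tbr.equation('X', 'Y')}")
    r = result.reg_ci_tbr
    lines.append(
        f"  R2_inliers = {r.r_squared:.4f}, F = {r.f_stat:.4g}, "
        f"p = {r.p:.4g}, VAR_error = {r.var_error:.3g}"
    )
    lines.append(f"TBR-on-iCA: {result.reg_ica_tbr.equation('iCA', 'TBR')} "
                 f"(R2 = {result.reg_ica_tbr.r_squared:.4f})")
    lines.append(f"RT-on-TBR (quadratic): {result.reg_rt_quad.equation('TBR', 'RT')} "
                 f"(p = {result.reg_rt_quad.p:.4g})")
    lines.append(f"RT-on-TBR linear slope: {result.reg_rt_linear.coefficients[1]:+.4f} s/unit")
    lines.append("")
    lines.append("Qualitative checks:")
    for name, ok in qualitative_checks(result).items():
        lines.append(f"  [{'PASS' if ok else 'FAIL'}] {name}")
    return "\n".join(lines) + "\n"


def qualitative_checks(result: AnalysisResult) -> dict[str, bool]:
    """The expected load pattern: TBR medians ordered rest > picking >
    coordination, positive CI→TBR slope, negative iCA→TBR slope, and
    response time rising as TBR falls."""
    q = dict(zip(result.quantiles["condition"], result.quantiles["q50"]))
    return {
        "median TBR ordering rest > picking > coordination": bool(
            q[REST] > q[PICKING] > q[COORDINATION]
        ),
        "positive CI -> TBR slope": bool(result.reg_ci_tbr.coefficients[1] > 0),
        "negative iCA -> TBR slope": bool(result.reg_ica_tbr.coefficients[1] < 0),
        "RT increases as TBR decreases": bool(result.reg_rt_linear.coefficients[1] < 0),
    }


def run_all(
    config: PipelineConfig | str | Path | None = None,
    out_dir: str | Path = "tacitload_out",
    seed: int | None = None,
) -> RunManifest:
    """Execute every stage in order, writing results and a manifest.

    Reruns with the same config and seed produce byte-identical CSVs.  A
    stage failure halts the run with the failing stage named; the partial
    manifest written so far is saved alongside.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    if seed is not None:
        config.generator.seed = int(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(), seed=config.generator.seed,
        version=__version__,
    )
    current = "simulate"
    try:
        session = simulate(config)
        outputs = [
            _write_csv(session.choices_picking.to_frame(), out_dir / "choices_picking.csv"),
            _write_csv(session.choices_coordination.to_frame(), out_dir / "choices_coordination.csv"),
        ]
        manifest.add_stage("simulate", outputs)

        current = "preprocess"
        band = extract_band_powers(session.recordings, config)
        manifest.add_stage("preprocess", [])  # epochs stay in memory here

        current = "extract-tbr"
        outputs = [_write_csv(band, out_dir / "bandpower.csv")]
        manifest.add_stage("extract-tbr", outputs)

        current = "metrics"
        scores = ci_table(session.choices_coordination)
        ci_path, ica_path = save_scores(scores, out_dir)
        manifest.add_stage("metrics", [(ci_path, _csv_rows(ci_path)),
                                       (ica_path, _csv_rows(ica_path))])

        current = "stats"
        result = analyze(band, session.choices_coordination, config)
        write_results(result, out_dir, config, manifest)

        current = "report"
        text = report_text(result, config)
        (out_dir / "report.txt").write_text(text)
        fig_path = plot_ci_tbr(result, out_dir / "fig_ci_tbr.png")
        manifest.add_stage("report", [(out_dir / "report.txt", 0), (fig_path, 0)])
    except Exception as err:
        manifest.add_stage("FAILED:" + current, [])
        manifest.save(out_dir / "manifest.json")
        raise RuntimeError(f"pipeline stage {current!r} failed: {err}") from err
    manifest.save(out_dir / "manifest.json")
    validate_manifest(manifest)
    return manifest


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _cmd_simulate(args, config: PipelineConfig) -> None:
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session = simulate(config)
    for rec in session.recordings:
        save_recording(rec, out / f"sub-{rec.subject:02d}.csv")
    save_choices(session.choices_picking, out / "choices_picking.csv")
    save_choices(session.choices_coordination, out / "choices_coordination.csv")
    (out / "session.json").write_text(json.dumps(
        {"rate": config.generator.sample_rate,
         "n_subjects": config.generator.n_subjects,
         "seed": config.generator.seed}
    ))
    print(f"wrote {config.generator.n_subjects} recordings to {out}")


def _cmd_preprocess(args, config: PipelineConfig) -> None:
    out = Path(args.out_dir)
    meta = json.loads((out / "session.json").read_text())
    for s in range(int(meta["n_subjects"])):
        rec = load_recording(out / f"sub-{s:02d}.csv", rate=float(meta["rate"]), subject=s)
        ica_seed = int(_stream(config.generator.seed, "ica", s).integers(2**31))
        epochs, _ = preprocess(rec, run_ica=config.run_ica, ica_seed=ica_seed)
        save_epochs(epochs, out / "epochs" / f"sub-{s:02d}")
    print(f"preprocessed {meta['n_subjects']} recordings")


def _cmd_extract(args, config: PipelineConfig) -> None:
    out = Path(args.out_dir)
    meta = json.loads((out / "session.json").read_text())
    frames = [
        band_power_table(load_epochs(out / "epochs" / f"sub-{s:02d}"))
        for s in range(int(meta["n_subjects"]))
    ]
    band = pd.concat(frames, ignore_index=True)
    band.to_csv(out / "bandpower.csv", index=False, float_format=_FLOAT_FMT)
    print(f"wrote {len(band)} band-power rows")


def _cmd_metrics(args, config: PipelineConfig) -> None:
    out = Path(args.out_dir)
    choices = load_choices(out / "choices_coordination.csv")
    scores = ci_table(choices)
    save_scores(scores, out)
    print("wrote ci.csv and ica.csv")


def _cmd_stats(args, config: PipelineConfig) -> None:
    out = Path(args.out_dir)
    band = pd.read_csv(out / "bandpower.csv")
    choices = load_choices(out / "choices_coordination.csv")
    result = analyze(band, choices, config)
    manifest = RunManifest(config_hash=config.config_hash(),
                           seed=config.generator.seed, version=__version__)
    write_results(result, out, config, manifest)
    print("wrote stats outputs")


def _cmd_report(args, config: PipelineConfig) -> None:
    out = Path(args.out_dir)
    band = pd.read_csv(out / "bandpower.csv")
    choices = load_choices(out / "choices_coordination.csv")
    result = analyze(band, choices, config)
    text = report_text(result, config)
    (out / "report.txt").write_text(text)
    plot_ci_tbr(result, out / "fig_ci_tbr.png")
    print(text)


def _cmd_run_all(args, config: PipelineConfig) -> None:
    manifest = run_all(config, args.out_dir)
    print(f"completed {len(manifest.stages)} stages; manifest in {args.out_dir}/manifest.json")


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(
        prog="tacitload",
        description="EEG theta/beta-ratio cognitive-load pipeline for tacit coordination games",
    )
    parser.add_argument("--config", default=None, help="key = value config file")
    parser.add_argument("--seed", type=int, default=None, help="overrides the config seed")
    parser.add_argument("--out-dir", default="tacitload_out")
    parser.add_argument("--channel", default=None, help="regression electrode (default F4)")
    parser.add_argument("--log-level", default="INFO")
    sub = parser.add_subparsers(dest="command", required=True)
    for name in ("simulate", "preprocess", "extract-tbr", "metrics", "stats",
                 "report", "run-all"):
        sub.add_parser(name)
    args = parser.parse_args(argv)
    logging.basicConfig(level=getattr(logging, args.log_level.upper(), logging.INFO))
    config = load_config(args.config)
    if args.seed is not None:
        config.generator.seed = args.seed
    if args.channel is not None:
        config.channel = args.channel
    dispatch = {
        "simulate": _cmd_simulate,
        "preprocess": _cmd_preprocess,
        "extract-tbr": _cmd_extract,
        "metrics": _cmd_metrics,
        "stats": _cmd_stats,
        "report": _cmd_report,
        "run-all": _cmd_run_all,
    }
    dispatch[args.command](args, config)
    return 0


if __name__ == "__main__":  # pragma: no cover
    sys.exit(main())
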
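"""Command-line entry points, tabular I/O, configuration and run manifests.

Input tables are comma-separated text with a header and columns ``time``
(positive reals, any consistent unit — the unit is carried through to every
grid and label unchanged), ``event`` (strictly 0/1; TRUE/FALSE or 1/2 coding
is rejected, never silently recoded) and ``marker`` (finite reals).

Every run writes ``manifest.json`` (inputs, resolved configuration, seed,
package and library versions) sufficient to reproduce deterministic outputs
bit for bit, plus a ``run.log``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import warnings
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._plots import (plot_auc_profile, plot_contour, plot_landmark_overlay,
                     plot_roc_derivative, plot_surface3d)
from .scale_invariant import DEFAULT_U_GRID, LandmarkSpec, landmark_profile
from .simulate import (SimulationConfig, normality_check, performance_study,
                       simulate_dataset)
from .surface import tdlr_bootstrap, tdlr_fit
from .survival_core import SurvivalDataset, cox_fit, km_estimate, ph_diagnostic
from .tdroc import roc_derivative, td_auc_profile, td_roc

log = logging.getLogger("tdlr")

REQUIRED_COLUMNS = ("time", "event", "marker")


def read_survival_table(path) -> SurvivalDataset:
    """Read and strictly validate a comma-separated survival table.

    Errors name the missing column or list the offending row numbers
    (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    bad = []
    time = pd.to_numeric(df["time"], errors="coerce")
    event = pd.to_numeric(df["event"], errors="coerce")
    marker = pd.to_numeric(df["marker"], errors="coerce")
    bad += list(df.index[~(np.isfinite(time) & (time > 0))] + 1)
    bad += list(df.index[~event.isin((0, 1))] + 1)
    bad += list(df.index[~np.isfinite(marker)] + 1)
    if bad:
        rows = ", ".join(str(r) for r in sorted(set(bad))[:20])
        raise ValueError(
            f"{path}: malformed rows {rows} (time must be > 0, event coded 0/1, "
            "marker finite)")
    return SurvivalDataset(time.to_numpy(), event.to_numpy(int), marker.to_numpy())


def _setup_run(output_dir, verbose: int) -> Path:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.handlers.clear()
    log.setLevel(logging.DEBUG if verbose else logging.INFO)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    sh = logging.StreamHandler(sys.stderr)
    sh.setLevel(logging.INFO if verbose else logging.WARNING)
    log.addHandler(fh)
    log.addHandler(sh)
    return out


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out: Path, command: str, config: dict, inputs) -> None:
    import lifelines
    import scipy
    manifest = {
        "command": command,
        "config": config,
        "inputs": [{"path": str(p), "sha256": _sha256(p)} for p in inputs],
        "versions": {
            "tdlr": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "lifelines": lifelines.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _load_config_file(config_path) -> dict:
    if config_path is None:
        return {}
    with open(config_path) as f:
        loaded = yaml.safe_load(f) or {}
    if not isinstance(loaded, dict):
        raise click.ClickException(f"{config_path}: config must be a mapping")
    return loaded


def _merge(file_cfg: dict, **flags) -> dict:
    """Flags override config-file values; None flags fall back to the file."""
    merged = dict(file_cfg)
    for k, v in flags.items():
        if v is not None:
            merged[k] = v
    return merged


def _parse_floats(text) -> np.ndarray | None:
    if text is None:
        return None
    if isinstance(text, (list, tuple, np.ndarray)):
        return np.asarray(text, dtype=float)
    return np.asarray([float(v) for v in str(text).split(",") if v != ""])


def _log_fit_summary(data: SurvivalDataset) -> None:
    model = cox_fit(data)
    log.info("n=%d, events=%d, censoring fraction=%.3f", len(data),
             data.n_events, data.censoring_fraction)
    log.info("Cox beta=%.4f (se %.4f)", model.beta, model.se_beta)
    try:
        diag = ph_diagnostic(model, data)
        log.info("PH diagnostic (Schoenfeld/km): stat=%.3f p=%.4f",
                 diag.statistic, diag.p_value)
        if diag.p_value < 0.05:
            log.warning("PH diagnostic p=%.4f < 0.05: the proportionality "
                        "assumption looks questionable; interpret with care",
                        diag.p_value)
    except Exception as exc:  # advisory only, never fatal
        log.warning("PH diagnostic unavailable: %s", exc)


@click.group()
@click.version_option(version=__version__)
def main() -> None:
    """Time-dependent likelihood ratio analysis for censored survival data."""


@main.command()
@click.argument("input_path", type=click.Path(exists=True))
@click.option("-o", "--output-dir", required=True, type=click.Path())
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--t-grid", default=None, help="comma-separated times")
@click.option("--x-grid", default=None, help="comma-separated marker values")
@click.option("--n-boot", type=int, default=None, help="bootstrap replicates (0 = none)")
@click.option("--level", type=float, default=None, help="confidence level")
@click.option("--seed", type=int, default=None)
@click.option("-v", "--verbose", count=True)
def surface(input_path, output_dir, config_path, t_grid, x_grid, n_boot, level,
            seed, verbose):
    """Estimate the log TD-LR surface, optionally with bootstrap bands."""
    out = _setup_run(output_dir, verbose)
    cfg = _merge(_load_config_file(config_path), t_grid=t_grid, x_grid=x_grid,
                 n_boot=n_boot, level=level, seed=seed)
    cfg.setdefault("n_boot", 0)
    cfg.setdefault("level", 0.95)
    cfg.setdefault("seed", 0)
    data = read_survival_table(input_path)
    _log_fit_summary(data)
    tg, xg = _parse_floats(cfg.get("t_grid")), _parse_floats(cfg.get("x_grid"))
    if cfg["n_boot"]:
        surf = tdlr_bootstrap(data, tg, xg, n_boot=int(cfg["n_boot"]),
                              level=float(cfg["level"]), seed=int(cfg["seed"]))
    else:
        surf = tdlr_fit(data, tg, xg)
    surf.to_frame().to_csv(out / "surface.csv", index=False)
    plot_surface3d(surf, out / "surface3d.png")
    plot_contour(surf, out / "contour.png")
    _write_manifest(out, "surface", cfg, [input_path])
    log.info("surface written to %s", out)


@main.command()
@click.argument("input_paths", nargs=-1, required=True,
                type=click.Path(exists=True))
@click.option("-o", "--output-dir", required=True, type=click.Path())
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--landmarks", default=None, help="comma-separated landmark times")
@click.option("--horizon", type=float, default=None)
@click.option("--u-grid", default=None, help="comma-separated placement values")
@click.option("--covariate", type=click.Choice(["probit", "raw"]), default=None)
@click.option("-v", "--verbose", count=True)
def landmark(input_paths, output_dir, config_path, landmarks, horizon, u_grid,
             covariate, verbose):
    """Scale-invariant landmark TD-LR profiles; give two inputs to overlay markers."""
    out = _setup_run(output_dir, verbose)
    cfg = _merge(_load_config_file(config_path), landmarks=landmarks,
                 horizon=horizon, u_grid=u_grid, covariate=covariate)
    cfg.setdefault("landmarks", "0")
    cfg.setdefault("horizon", 2.0)
    cfg.setdefault("covariate", "probit")
    spec = LandmarkSpec(_parse_floats(cfg["landmarks"]), float(cfg["horizon"]))
    ug = _parse_floats(cfg.get("u_grid"))
    ug = DEFAULT_U_GRID if ug is None else ug
    profiles = []
    for path in input_paths:
        data = read_survival_table(path)
        _log_fit_summary(data)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", RuntimeWarning)
            prof = landmark_profile(data, spec, ug, covariate=cfg["covariate"],
                                    marker_id=Path(path).stem)
        for w in caught:
            log.warning("%s: %s", path, w.message)
        profiles.append(prof)
    table = pd.concat(profiles, ignore_index=True)
    table.to_csv(out / "landmark_profile.csv", index=False)
    if not table.empty:
        plot_landmark_overlay(table, out / "landmark_overlay.png")
    _write_manifest(out, "landmark", cfg, list(input_paths))
    log.info("landmark profile written to %s", out)


@main.command()
@click.argument("input_path", type=click.Path(exists=True))
@click.option("-o", "--output-dir", required=True, type=click.Path())
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--times", default=None, help="comma-separated evaluation times")
@click.option("--bandwidth", type=float, default=None, help="derivative smoothing bandwidth")
@click.option("-v", "--verbose", count=True)
def roc(input_path, output_dir, config_path, times, bandwidth, verbose):
    """Time-dependent ROC curves, AUC(t) profile and smoothed ROC derivative."""
    out = _setup_run(output_dir, verbose)
    cfg = _merge(_load_config_file(config_path), times=times, bandwidth=bandwidth)
    cfg.setdefault("bandwidth", 0.1)
    data = read_survival_table(input_path)
    _log_fit_summary(data)
    tvals = _parse_floats(cfg.get("times"))
    if tvals is None:
        tvals = np.percentile(data.time[data.event == 1], [25, 50, 75])
        cfg["times"] = list(tvals)
    rows, curves = [], {}
    for t in tvals:
        curve = roc_derivative(td_roc(data, float(t)), float(cfg["bandwidth"]))
        curves[f"t={t:g}"] = curve
        for f, tp, dv in zip(curve.fpr, curve.tpr, curve.derivative):
            rows.append((t, f, tp, dv))
    pd.DataFrame(rows, columns=["t", "fpr", "tpr", "derivative"]).to_csv(
        out / "roc_curves.csv", index=False)
    prof = td_auc_profile(data, tvals)
    prof.to_csv(out / "auc_profile.csv", index=False)
    plot_auc_profile({"marker": prof}, out / "auc_profile.png")
    plot_roc_derivative(curves, out / "roc_derivative.png")
    _write_manifest(out, "roc", cfg, [input_path])
    log.info("ROC outputs written to %s", out)


@main.command()
@click.option("-o", "--output-dir", required=True, type=click.Path())
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--n", type=int, default=None)
@click.option("--beta", type=float, default=None)
@click.option("--gamma", type=float, default=None)
@click.option("--event-scale", type=float, default=None)
@click.option("--censor-scale", type=float, default=None)
@click.option("--max-followup", type=float, default=None)
@click.option("--seed", type=int, default=None)
@click.option("--n-reps", type=int, default=None)
@click.option("--study/--no-study", default=False,
              help="also run the bias/MSE performance study")
@click.option("--eval-points", default="2,-1;2,0;8,1",
              help="semicolon-separated t,x pairs for the study")
@click.option("--histograms/--no-histograms", default=False,
              help="write sampling-distribution histograms per eval point")
@click.option("-v", "--verbose", count=True)
def simulate(output_dir, config_path, n, beta, gamma, event_scale, censor_scale,
             max_followup, seed, n_reps, study, eval_points, histograms, verbose):
    """Draw a synthetic dataset; optionally run the bias/MSE performance study."""
    out = _setup_run(output_dir, verbose)
    cfg = _merge(_load_config_file(config_path), n=n, beta=beta, gamma=gamma,
                 event_scale=event_scale, censor_scale=censor_scale,
                 max_followup=max_followup, seed=seed, n_reps=n_reps)
    known = {f.name for f in SimulationConfig.__dataclass_fields__.values()}
    sim_cfg = SimulationConfig(**{k: v for k, v in cfg.items() if k in known})
    data = simulate_dataset(sim_cfg)
    pd.DataFrame({"time": data.time, "event": data.event,
                  "marker": data.marker}).to_csv(out / "dataset.csv", index=False)
    log.info("simulated n=%d, events=%d, censoring fraction=%.3f",
             len(data), data.n_events, data.censoring_fraction)
    with open(out / "config.yaml", "w") as f:
        yaml.safe_dump({k: getattr(sim_cfg, k) for k in known}, f)
    points = [tuple(float(v) for v in pair.split(","))
              for pair in str(eval_points).split(";") if pair]
    if study:
        table = performance_study([sim_cfg], points)
        table.to_csv(out / "performance.csv", index=False)
        log.info("performance study written (%d rows)", len(table))
    if histograms:
        summary = normality_check(sim_cfg, points,
                                  max(sim_cfg.n_reps, 200), output_dir=out)
        summary.to_csv(out / "normality.csv", index=False)
    _write_manifest(out, "simulate", cfg, [])
    log.info("simulation outputs written to %s", out)


if __name__ == "__main__":
    main()
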
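"""Configuration-driven experiment runner.

An :class:`ExperimentConfig` describes one sweep of the repolarization-
reserve plane: geometry, the (gkr_mult, gcal_mult) points, the initiation
protocol, numerics, and which analyses to run.  ``run_experiment``
executes every point, attaches provenance (config hash), and writes
movies, spectra, the eta table (rows = gkr_mult, columns = gcal_mult),
filament tables, regime labels and electrograms to the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cell_model import build_params
from .ecg import compute_pseudo_ecg, ecg_to_csv, hemisphere_electrodes
from .metrics import average_spectrum, classify_pattern, eta_index
from .movie import VoltageMovie
from .phase import filament_table, phase_movie, track_filaments
from .protocols import (ProtocolSpec, run_burst_pacing, run_decoupling_test,
                        run_s1s2)
from .tissue import build_grid, conductivity_from_fibers

__all__ = ["ExperimentConfig", "run_experiment", "load_config", "save_config"]


@dataclass
class ExperimentConfig:
    """Serializable description of one experiment or sweep."""

    geometry: dict = field(default_factory=lambda: {
        "kind": "sheet", "extents": [4.0, 4.0], "dx": 0.04})
    points: list = field(default_factory=lambda: [[1.0, 1.0]])
    protocol: dict = field(default_factory=lambda: {"kind": "burst"})
    numerics: dict = field(default_factory=lambda: {
        "dt": 0.02, "sample_dt": 1.0})
    conductivity: dict = field(default_factory=lambda: {
        "dl": 0.00154, "dt_ratio": 4.0})
    analyses: list = field(default_factory=lambda: [
        "spectrum", "eta", "classify"])
    analysis_window: float = 1000.0   # final ms analyzed
    outdir: str = "results"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        return ExperimentConfig.from_dict(yaml.safe_load(fh))


def save_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def _analysis_bundle(movie, window_ms, analyses, grid, cond, params,
                     states):
    out = {}
    t_end = movie.t0 + movie.duration
    last = movie.window(t_end - window_ms, t_end)
    if "spectrum" in analyses:
        out["spectrum"] = average_spectrum(last, window=window_ms)
    if "eta" in analyses:
        out["eta"] = eta_index(last, window=window_ms)
    if "filaments" in analyses:
        try:
            out["filaments"] = track_filaments(phase_movie(last))
        except ValueError:
            out["filaments"] = []
    if "decouple" in analyses:
        planes = [(a, (s - 1) * grid.dx / 2)
                  for a, s in enumerate(grid.shape)]
        out["decouple"] = run_decoupling_test(states, grid, params, planes,
                                              cond=cond)
    if "classify" in analyses:
        out["label"] = classify_pattern(
            last, out.get("spectrum"), out.get("eta"),
            out.get("filaments"), out.get("decouple"))
    if "ecg" in analyses:
        electrodes = hemisphere_electrodes(grid)
        out["ecg"] = compute_pseudo_ecg(last, grid, cond, electrodes)
        out["ecg_times"] = last.times
    return out


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute the configured sweep; returns {point: result dict}.

    Failures at single parameter points are recorded and the sweep
    continues.  All outputs are deterministic for a fixed config.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": cfg.config_hash(), "version": __version__}
    save_config(cfg, outdir / "config.yaml")

    geo = dict(cfg.geometry)
    grid = build_grid(geo.pop("kind"), geo.pop("extents"),
                      geo.pop("dx", 0.04), **geo)
    cond = conductivity_from_fibers(grid, **cfg.conductivity)
    results = {}
    eta_rows = {}
    labels = {}
    for gkr, gcal in cfg.points:
        key = f"gkr{gkr:g}_gcal{gcal:g}"
        try:
            params = build_params(gkr, gcal)
            proto = dict(cfg.protocol)
            kind = proto.pop("kind", "burst")
            spec = ProtocolSpec(kind=kind,
                                sample_dt=cfg.numerics.get("sample_dt", 1.0),
                                **proto)
            if kind == "burst":
                sim = run_burst_pacing(grid, params, spec, cond=cond,
                                       dt=cfg.numerics.get("dt", 0.02))
                movie, states = sim.movie, sim.states
            elif kind == "s1s2":
                s = run_s1s2(grid, params, spec, cond=cond,
                             dt=cfg.numerics.get("dt", 0.02))
                movie, states = s.movie, s.states
            else:
                raise ValueError(f"unknown protocol kind {kind!r}")

            bundle = _analysis_bundle(movie, cfg.analysis_window,
                                      cfg.analyses, grid, cond, params,
                                      states)
            results[key] = {"movie": movie, **bundle}

            movie.meta.update(provenance)
            movie.save(outdir / f"movie_{key}")
            if "eta" in bundle:
                eta_rows.setdefault(gkr, {})[gcal] = bundle["eta"].eta
            if "label" in bundle:
                labels[key] = {"label": bundle["label"].label,
                               "low_confidence":
                                   bundle["label"].low_confidence}
            if "spectrum" in bundle:
                import pandas as pd
                sp = bundle["spectrum"]
                pd.DataFrame({"freq_hz": sp.freqs,
                              "amplitude": sp.mean_amplitude}).to_csv(
                    outdir / f"spectrum_{key}.csv", index=False)
            if "filaments" in bundle:
                filament_table(bundle["filaments"]).to_csv(
                    outdir / f"filaments_{key}.csv", index=False)
            if "ecg" in bundle:
                ecg_to_csv(bundle["ecg"], bundle["ecg_times"],
                           outdir / f"ecg_{key}.csv")
        except Exception as exc:  # sweep continues past single-point failures
            results[key] = {"error": repr(exc)}
    if eta_rows:
        import pandas as pd
        df = pd.DataFrame(eta_rows).T.sort_index()
        df.index.name = "gkr_mult"
        df.to_csv(outdir / "eta_table.csv")
    (outdir / "labels.json").write_text(json.dumps(
        {"provenance": provenance, "labels": labels}, indent=1))
    return results
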
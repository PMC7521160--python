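"""End-to-end orchestration of the ripple analysis pipeline.

Synthesize (or load) a two-channel NREM recording, preprocess it, and
run every analysis stage: adjusted power spectra, wavelet decomposition,
AEC/PLV connectivity, same- and cross-site PAC comodulograms, ripple
detection and characterization, cross-channel co-occurrence, and
ripple-locked ERP/power/ITPC maps.  All randomness flows from one
master seed; outputs are plain delimited tables plus a JSON summary
carrying the seed and a config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as swio
from .connectivity import connectivity_table
from .cooccurrence import cooccurrence_table
from .locked import LockedMaps, locked_analyses
from .pac import (PacGrid, comodulogram, pac_significance,
                  ripple_band_modulation_profile)
from .preprocess import Recording, preprocess
from .ripples import (detect_ripples, make_surrogate_events,
                      ripple_properties)
from .spectral import adjust_one_over_f, welch_psd
from .synth import CHANNELS, SynthConfig, generate_recording
from .timefreq import build_wavelets, decompose_trials, segment_60s

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    synth: SynthConfig | None = field(default_factory=SynthConfig)
    edf_path: str | None = None
    stages_path: str | None = None
    channel_pair: tuple[str, str] = CHANNELS
    seed: int = 0
    out_dir: str | None = None
    n_surrogate_sets: int = 1000
    n_timeshift_surrogates: int = 100
    run_connectivity: bool = True
    run_pac: bool = True
    run_locked: bool = True
    #: compute PAC on every k-th centre frequency (1 = full 50x50 grid)
    pac_freq_step: int = 1

    def content_hash(self) -> str:
        payload = {k: v for k, v in vars(self).items() if k != "out_dir"}
        if self.synth is not None:
            payload["synth"] = vars(self.synth)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    """All stage outputs of one run."""

    config: RunConfig
    recording: Recording
    trials: list
    spectra: dict[str, Any]
    ripple_tables: dict[str, pd.DataFrame]
    events: dict[str, list]
    surrogates: dict[str, Any]
    connectivity: pd.DataFrame | None
    pac_grids: dict[str, PacGrid]
    pac_clusters: dict[str, list]
    pac_profiles: dict[str, tuple]
    cooccurrence: pd.DataFrame | None
    locked: dict[str, LockedMaps]
    summary: dict


def _ripple_summary(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    rows = []
    for ch, tab in tables.items():
        if len(tab):
            rows.append({
                "channel": ch,
                "n_events": tab.attrs["n_events"],
                "density_per_min": tab.attrs["density_per_min"],
                "duration_ms_mean": tab["duration_ms"].mean(),
                "duration_ms_sd": tab["duration_ms"].std(),
                "main_freq_hz_mean": tab["main_freq_hz"].mean(),
                "main_freq_hz_sd": tab["main_freq_hz"].std(),
                "amplitude_uv_mean": tab["amplitude_uv"].mean(),
                "amplitude_uv_sd": tab["amplitude_uv"].std(),
            })
        else:
            rows.append({"channel": ch, "n_events": 0,
                         "density_per_min": 0.0})
    return pd.DataFrame(rows)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every enabled stage; deterministic given ``config.seed``.

    A failing stage raises :class:`StageError` naming the stage.
    """
    stage = {"name": "setup"}
    try:
        return _run_pipeline(config, stage)
    except Exception as exc:
        raise StageError(f"stage '{stage['name']}' failed: {exc}") from exc


def _run_pipeline(config: RunConfig, stage: dict) -> PipelineResult:
    rng = np.random.default_rng(config.seed)
    (conn_rng, pac_rng, surr_rng) = rng.spawn(3)

    # --- input ---------------------------------------------------------
    stage["name"] = "input"
    if config.edf_path is not None:
        channels, fs = swio.read_edf(config.edf_path)
        stages = (swio.read_stages(config.stages_path)
                  if config.stages_path else
                  ["N2"] * int(np.ceil(
                      len(next(iter(channels.values()))) / (20 * fs))))
        truth = None
    else:
        synth = config.synth
        if synth is None:
            raise ValueError("provide either synth config or an EDF path")
        channels, truth = generate_recording(synth)
        fs = synth.fs
        stages = ["N2"] * int(np.ceil(synth.duration_s / 20.0))
    ch_a, ch_b = config.channel_pair
    raw = Recording(channels={ch_a: channels[ch_a], ch_b: channels[ch_b]},
                    fs=fs, stages=stages)

    # --- preprocess ----------------------------------------------------
    stage["name"] = "preprocess"
    clean, trials = preprocess(raw)
    if not trials:
        raise RuntimeError("preprocess: no artifact-free trials")
    clean_minutes = sum(t.duration_s(fs) for t in trials) / 60.0

    # --- spectra -------------------------------------------------------
    stage["name"] = "spectra"
    spectra: dict[str, Any] = {}
    for ch in (ch_a, ch_b):
        spec = welch_psd(trials, clean.channels[ch], fs)
        spectra[ch] = (spec, adjust_one_over_f(spec))

    # --- time-frequency ------------------------------------------------
    stage["name"] = "timefreq"
    family = build_wavelets(fs)
    runs = {ch: decompose_trials(clean.channels[ch], fs, trials, family,
                                 channel=ch) for ch in (ch_a, ch_b)}
    segments = {ch: [s for stage in ("N2", "N3")
                     for s in segment_60s(runs[ch], stage)]
                for ch in (ch_a, ch_b)}

    # --- connectivity --------------------------------------------------
    stage["name"] = "connectivity"
    conn = None
    if config.run_connectivity and segments[ch_a]:
        conn = connectivity_table(segments[ch_a], segments[ch_b],
                                  family.center_freqs,
                                  n_surr=config.n_timeshift_surrogates,
                                  seed=conn_rng)

    # --- PAC -----------------------------------------------------------
    stage["name"] = "pac"
    pac_grids: dict[str, PacGrid] = {}
    pac_clusters: dict[str, list] = {}
    pac_profiles: dict[str, tuple] = {}
    if config.run_pac and segments[ch_a]:
        step = max(1, config.pac_freq_step)
        fidx = np.arange(0, len(family.center_freqs), step)
        modes = {
            f"same_{ch_a}": (ch_a, ch_a),
            f"same_{ch_b}": (ch_b, ch_b),
            f"cross_{ch_a}_phase": (ch_a, ch_b),
            f"cross_{ch_b}_phase": (ch_b, ch_a),
        }
        for name, (phase_ch, amp_ch) in modes.items():
            grid = comodulogram(segments[phase_ch], segments[amp_ch],
                                family.center_freqs, site=name,
                                n_surr=config.n_timeshift_surrogates,
                                seed=pac_rng, f1_indices=fidx,
                                f2_indices=fidx)
            pac_grids[name] = grid
            if grid.dpac_z.shape[0] >= 3:
                pac_clusters[name] = pac_significance(grid, seed=pac_rng)
            pac_profiles[name] = ripple_band_modulation_profile(grid)

    # --- ripples -------------------------------------------------------
    stage["name"] = "ripples"
    events, surrogates, tables = {}, {}, {}
    for ch in (ch_a, ch_b):
        ev = detect_ripples(clean.channels[ch], fs, trials, channel=ch)
        events[ch] = ev
        tables[ch] = ripple_properties(ev, clean.channels[ch], fs,
                                       clean_minutes)
        surrogates[ch] = make_surrogate_events(
            ev, trials, clean.n_samples, fs,
            n_sets=config.n_surrogate_sets, seed=surr_rng)

    # --- co-occurrence -------------------------------------------------
    stage["name"] = "cooccurrence"
    cooc = None
    if events[ch_a] and events[ch_b]:
        cooc = cooccurrence_table(events[ch_a], events[ch_b],
                                  surrogates[ch_a], surrogates[ch_b], fs,
                                  label_a=ch_a, label_b=ch_b)

    # --- ripple-locked maps --------------------------------------------
    stage["name"] = "locked"
    locked: dict[str, LockedMaps] = {}
    if config.run_locked:
        pairings = {
            f"{ch_a}_ripples_{ch_a}_signal": (ch_a, ch_a),
            f"{ch_b}_ripples_{ch_b}_signal": (ch_b, ch_b),
            f"{ch_a}_ripples_{ch_b}_signal": (ch_a, ch_b),
            f"{ch_b}_ripples_{ch_a}_signal": (ch_b, ch_a),
        }
        for name, (ev_ch, sig_ch) in pairings.items():
            if events[ev_ch]:
                locked[name] = locked_analyses(
                    clean.channels[sig_ch], runs[sig_ch], events[ev_ch],
                    surrogates[ev_ch], fs)

    stage["name"] = "report"
    summary = {
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "fs": fs,
        "clean_minutes": clean_minutes,
        "n_trials": len(trials),
        "n_segments": len(segments[ch_a]),
        "ripples": _ripple_summary(tables).to_dict(orient="records"),
        "cooccurrence": (cooc.to_dict(orient="records")
                         if cooc is not None else []),
    }
    result = PipelineResult(
        config=config, recording=clean, trials=trials, spectra=spectra,
        ripple_tables=tables, events=events, surrogates=surrogates,
        connectivity=conn, pac_grids=pac_grids, pac_clusters=pac_clusters,
        pac_profiles=pac_profiles, cooccurrence=cooc, locked=locked,
        summary=summary)
    if config.out_dir:
        _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    header = {"seed": result.config.seed,
              "config_hash": result.config.content_hash()}
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1, default=float)
    for ch, (spec, adj) in result.spectra.items():
        pd.DataFrame({"freq_hz": spec.freqs, "power": spec.power}).to_csv(
            out / f"spectrum_{ch}.csv", index=False)
        pd.DataFrame({"freq_hz": adj.freqs_log,
                      "adjusted_power": adj.adjusted_power}).to_csv(
            out / f"spectrum_adjusted_{ch}.csv", index=False)
    for ch, tab in result.ripple_tables.items():
        tab.to_csv(out / f"ripples_{ch}.csv", index=False)
    if result.connectivity is not None:
        result.connectivity.to_csv(out / "connectivity.csv", index=False)
    if result.cooccurrence is not None:
        result.cooccurrence.to_csv(out / "cooccurrence.csv", index=False)
    for name, (f1, curve) in result.pac_profiles.items():
        pd.DataFrame({"f1_hz": f1, "mean_dpac_z": curve}).to_csv(
            out / f"pac_profile_{name}.csv", index=False)
    for name, grid in result.pac_grids.items():
        _comodulogram_table(grid, result.pac_clusters.get(name, [])).to_csv(
            out / f"comodulogram_{name}.csv", index=False)
    from .stats import cluster_report
    for name, lm in result.locked.items():
        for kind, clusters in (("power", lm.power_clusters),
                               ("itpc", lm.itpc_clusters)):
            cluster_report(clusters, lm.tf_freqs, lm.tf_t * 1000.0).to_csv(
                out / f"locked_{kind}_clusters_{name}.csv", index=False)
    with open(out / "run_header.json", "w") as fh:
        json.dump(header, fh)


def _comodulogram_table(grid: PacGrid, clusters: list) -> pd.DataFrame:
    """(f1_hz, f2_hz, mean_dpac_z, t_stat, in_cluster) over the grid."""
    import warnings

    n = grid.dpac_z.shape[0]
    with warnings.catch_warnings(), \
            np.errstate(invalid="ignore", divide="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs
        mean_z = np.nanmean(grid.dpac_z, axis=0)
        if n > 1:
            t = (mean_z / (np.nanstd(grid.dpac_z, axis=0, ddof=1)
                           / np.sqrt(n)))
        else:
            t = np.full_like(mean_z, np.nan)
    in_cluster = np.zeros(mean_z.shape, dtype=bool)
    for c in clusters:
        in_cluster[c.members[:, 0], c.members[:, 1]] = True
    i1, i2 = np.nonzero(np.isfinite(mean_z))
    return pd.DataFrame({
        "f1_hz": grid.f1[i1], "f2_hz": grid.f2[i2],
        "mean_dpac_z": mean_z[i1, i2], "t_stat": t[i1, i2],
        "in_cluster": in_cluster[i1, i2],
    })
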
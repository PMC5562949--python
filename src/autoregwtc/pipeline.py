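"""End-to-end analysis: recording -> segments -> coherence -> index.

One call, :func:`run_pipeline`, composes the whole monitoring analysis:

1. spike removal on both signals,
2. segmentation at recording gaps (keeping runs long enough to support the
   largest analysis scale),
3. per-segment polynomial detrending,
4. per-segment Morlet wavelet coherence and AR1 Monte-Carlo significance,
5. pooling of significant in-phase time across segments into P(s) and the
   scalar index Pmean over the 8-32 min band.

All randomness (surrogate ensembles) derives from one top-level seed; the
returned report carries every setting needed to reproduce the numbers.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Any

import numpy as np
import yaml

from . import __version__
from .index import PhaseBin, ScaleProfile, autoreg_index, percent_significant
from .preprocess import (
    PhysioSeries,
    detrend_poly2,
    read_physio_csv,
    remove_spikes,
    segment_valid,
)
from .significance import estimate_ar1, significance_map
from .wavelet import SmoothingSpec, WaveletParams, WTCField, coherence

__all__ = ["default_config", "load_config", "run_pipeline", "run_cohort"]


class InsufficientDataError(ValueError):
    """No contiguous jointly-valid run is long enough to analyze."""


def default_config() -> dict[str, Any]:
    """Default settings for every stage, as one nested mapping."""
    return {
        "preprocess": {"spike_z": 5.0, "min_segment_len": 256, "detrend_degree": 2},
        "wavelet": {"omega0": 6.0, "s0": 2.0, "dj": 1.0 / 12.0, "max_period": 64.0},
        "smoothing": {"time_sigma_scales": 1.0, "scale_octaves": 0.6},
        "significance": {"n_surrogates": 300, "alpha": 0.05},
        "index": {"band": [8.0, 32.0], "phase": "in_phase"},
        # weight factors of the validated neuroimaging scoring system; no
        # defensible default exists, so scoring raw severities requires them
        "neuro_weights": {"bleeding": None, "parenchymal": None, "ventricular": None},
    }


def load_config(path=None) -> dict[str, Any]:
    """Merge a YAML/JSON config file over the defaults (shallow, per section)."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError("config file must contain a mapping")
    for section, values in user.items():
        if section not in cfg:
            raise ValueError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        unknown = set(values) - set(cfg[section])
        if unknown:
            raise ValueError(f"unknown keys in {section!r}: {sorted(unknown)}")
        cfg[section].update(values)
    return cfg


def _wavelet_objects(cfg: dict[str, Any]) -> tuple[WaveletParams, SmoothingSpec]:
    w = cfg["wavelet"]
    s = cfg["smoothing"]
    return (
        WaveletParams(omega0=w["omega0"], s0=w["s0"], dj=w["dj"], max_period=w["max_period"]),
        SmoothingSpec(time_sigma_scales=s["time_sigma_scales"], scale_octaves=s["scale_octaves"]),
    )


def analyze_pair(
    map_series: PhysioSeries,
    scto2_series: PhysioSeries,
    config: dict[str, Any] | None = None,
    seed: int | None = None,
) -> tuple[ScaleProfile, list[WTCField], list, list]:
    """Run stages 1-5 on an in-memory pair; returns profile and per-segment pieces."""
    cfg = config or default_config()
    pp = cfg["preprocess"]
    params, spec = _wavelet_objects(cfg)
    sig_cfg = cfg["significance"]

    map_clean = remove_spikes(map_series, pp["spike_z"])
    scto2_clean = remove_spikes(scto2_series, pp["spike_z"])
    segments = segment_valid((map_clean, scto2_clean), pp["min_segment_len"])
    if not segments:
        raise InsufficientDataError(
            "insufficient contiguous data: no jointly-valid run of length "
            f">= {pp['min_segment_len']} min"
        )

    seeds = np.random.SeedSequence(seed).spawn(len(segments))
    fields, sigs = [], []
    for seg, seg_seed in zip(segments, seeds):
        dt = map_clean.dt
        sub_t = map_clean.timestamps[seg.slice()]
        x = detrend_poly2(
            dataclasses.replace(map_clean, timestamps=sub_t,
                                values=map_clean.values[seg.slice()],
                                valid_mask=map_clean.valid_mask[seg.slice()]),
            pp["detrend_degree"],
        ).values
        y = detrend_poly2(
            dataclasses.replace(scto2_clean, timestamps=sub_t,
                                values=scto2_clean.values[seg.slice()],
                                valid_mask=scto2_clean.valid_mask[seg.slice()]),
            pp["detrend_degree"],
        ).values
        field = coherence(x, y, dt, params, spec, times=sub_t)
        rng = np.random.default_rng(seg_seed)
        sig = significance_map(
            field,
            estimate_ar1(x),
            estimate_ar1(y),
            n_surrogates=sig_cfg["n_surrogates"],
            alpha=sig_cfg["alpha"],
            seed=rng,
        )
        fields.append(field)
        sigs.append(sig)
    profile = percent_significant(fields, sigs, segments)
    return profile, fields, sigs, segments


def run_pipeline(
    physio_csv,
    config: dict[str, Any] | None = None,
    seed: int | None = None,
    patient_id: str | None = None,
) -> dict[str, Any]:
    """Full analysis of one physiological CSV; returns the run report.

    The report is a JSON-serializable mapping with the per-phase-bin scale
    profile, the autoregulation index, all analysis settings, the software
    version and the seed.
    """
    cfg = config or default_config()
    map_series, scto2_series = read_physio_csv(physio_csv)
    profile, fields, sigs, segments = analyze_pair(map_series, scto2_series, cfg, seed)
    band = tuple(cfg["index"]["band"])
    phase = PhaseBin(cfg["index"]["phase"])
    idx = autoreg_index(profile, band=band, phase=phase)
    usable_minutes = float(sum(len(s) for s in segments)) * map_series.dt
    return {
        "patient_id": patient_id or str(physio_csv),
        "software_version": __version__,
        "seed": seed,
        "settings": {
            k: cfg[k] for k in ("preprocess", "wavelet", "smoothing", "significance", "index")
        },
        "segments": {
            "count": len(segments),
            "bounds": [[s.start, s.end] for s in segments],
            "total_minutes": usable_minutes,
        },
        "scale_profile": {
            "period_min": profile.periods.tolist(),
            "usable_count": profile.usable_count.tolist(),
            **{
                f"P_{b.value}": np.where(
                    np.isfinite(profile.p[b]), profile.p[b], None
                ).tolist()
                for b in PhaseBin
            },
        },
        "autoreg_index": {
            "pmean_pct": idx.pmean,
            "band_min": list(idx.band),
            "phase_bin": idx.phase.value,
            "n_scales_in_band": idx.n_scales_in_band,
        },
    }


def run_cohort(
    config: dict[str, Any] | None = None,
    tables: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Cohort-level report: correlation, regressions and category counts."""
    from .cohort import cohort_report, load_cohort

    df = load_cohort(**(tables or {}))
    report = cohort_report(df)
    report["software_version"] = __version__
    return report


def report_to_markdown(report: dict[str, Any]) -> str:
    """Human-readable summary of a run report."""
    lines = [
        f"# Autoregulation run report — {report['patient_id']}",
        "",
        f"- software: autoregwtc {report['software_version']}, seed {report['seed']}",
        f"- segments: {report['segments']['count']} "
        f"({report['segments']['total_minutes']:.0f} usable minutes)",
        f"- autoregulation index Pmean: "
        f"**{report['autoreg_index']['pmean_pct']:.1f}%** "
        f"({report['autoreg_index']['phase_bin']} coherence, "
        f"{report['autoreg_index']['band_min'][0]:.0f}-"
        f"{report['autoreg_index']['band_min'][1]:.0f} min band)",
        "",
        "Settings:",
        "",
        "```yaml",
        yaml.safe_dump(report["settings"], sort_keys=False).rstrip(),
        "```",
    ]
    return "\n".join(lines) + "\n"


def save_field(path, field: WTCField, sig=None) -> None:
    """Serialize a coherence field (and optional significance) to ``.npz`` + JSON sidecar."""
    arrays = {
        "times": field.times,
        "scales": field.scales,
        "periods": field.periods,
        "r2": field.r2,
        "phase": field.phase,
        "coi": field.coi,
    }
    if sig is not None:
        arrays["critical_r2"] = sig.critical
        arrays["sig_mask"] = sig.sig_mask
    np.savez_compressed(path, **arrays)
    sidecar = {
        "wavelet": dataclasses.asdict(field.params),
        "smoothing": dataclasses.asdict(field.smoothing),
    }
    if sig is not None:
        sidecar["significance"] = {
            "alpha": sig.alpha,
            "n_surrogates": sig.n_surrogates,
        }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
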
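"""Delimited-text I/O, run configuration, and the end-to-end pipeline driver.

Everything on disk is delimited text for diff-ability: connectomes and
time-series matrices as CSV, metadata as small key-value sidecars, result
tables with headers.  A run never mutates its inputs; all outputs go into a
run directory together with the resolved configuration and the seeds used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import gsp, prep, stats, surrogates as surr
from .graph import eigendecompose, load_connectome, normalized_laplacian
from .gsp import RegionTimeSeries, SdiMap, TimeResolvedSdi

__all__ = [
    "RunConfig",
    "SubjectSpec",
    "load_timeseries",
    "save_timeseries",
    "save_sdi_map",
    "save_time_resolved",
    "run_pipeline",
]

logger = logging.getLogger("neurogsp")


def load_timeseries(path: str, region_count: int | None = None) -> RegionTimeSeries:
    """Read a regions-by-samples delimited matrix plus its ``.meta`` sidecar.

    The sidecar (``<path>.meta``, YAML key-value) must define
    ``sampling_rate`` and may define ``subject_id``, ``condition`` and
    ``signal_kind``.
    """
    from .graph import _sniff_delimiter

    values = np.loadtxt(path, delimiter=_sniff_delimiter(path), ndmin=2)
    meta_path = path + ".meta"
    meta: dict = {}
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    if "sampling_rate" not in meta:
        raise ValueError(f"missing sidecar {meta_path!r} with a sampling_rate")
    ts = RegionTimeSeries(
        values=values,
        sampling_rate=float(meta["sampling_rate"]),
        subject_id=str(meta.get("subject_id", "unknown")),
        condition=str(meta.get("condition", "unknown")),
        signal_kind=str(meta.get("signal_kind", "raw")),
    )
    if region_count is not None and ts.n_regions != region_count:
        raise ValueError(
            f"{path!r} has {ts.n_regions} regions, expected {region_count}"
        )
    return ts


def save_timeseries(ts: RegionTimeSeries, path: str) -> None:
    np.savetxt(path, ts.values, delimiter=",", fmt="%.17g")
    with open(path + ".meta", "w") as fh:
        yaml.safe_dump(
            {
                "sampling_rate": float(ts.sampling_rate),
                "subject_id": ts.subject_id,
                "condition": ts.condition,
                "signal_kind": ts.signal_kind,
            },
            fh,
        )


def save_sdi_map(sdi_map: SdiMap, region_ids: list[str], path: str) -> None:
    pd.DataFrame(
        {
            "region": region_ids,
            "sdi": sdi_map.sdi,
            "cutoff_C": sdi_map.cutoff_C,
        }
    ).to_csv(path, index=False)


def save_time_resolved(tr: TimeResolvedSdi, region_ids: list[str], path: str) -> None:
    df = pd.DataFrame(
        tr.sdi, index=pd.Index(region_ids, name="region"),
        columns=[f"w{w:04d}" for w in range(tr.n_windows)],
    )
    df.to_csv(path)
    pd.DataFrame(
        {"window": np.arange(tr.n_windows), "cutoff_C": tr.per_window_cutoffs}
    ).to_csv(os.path.splitext(path)[0] + "_cutoffs.csv", index=False)


@dataclass
class SubjectSpec:
    """Paths for one subject: a connectome and one time series per condition."""

    subject_id: str
    connectome: str
    timeseries: dict[str, str]  # condition -> path


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    subjects: list[SubjectSpec]
    out_dir: str
    region_table: str | None = None
    bands: list[str] = field(default_factory=list)  # empty -> raw signal only
    resample_hz: float | None = None
    k_surrogates: int = 19
    seed: int = 0
    alpha_group: float = 0.05
    p_success: float = 0.05
    window_seconds: float = 1.0
    time_resolved: bool = False
    contrast: tuple[str, str] | None = None
    alpha_contrast: float = 0.05

    def validate(self) -> None:
        if not self.subjects:
            raise ValueError("config lists no subjects")
        if self.k_surrogates < 1:
            raise ValueError("k_surrogates must be >= 1")
        if not (0 < self.alpha_group < 1 and 0 < self.p_success < 1):
            raise ValueError("probabilities must be in (0, 1)")
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        for band in self.bands:
            if band not in prep.STANDARD_BANDS:
                raise ValueError(
                    f"unknown band {band!r}; known: {sorted(prep.STANDARD_BANDS)}"
                )
        conditions = {c for s in self.subjects for c in s.timeseries}
        if self.contrast is not None and not set(self.contrast) <= conditions:
            raise ValueError(f"contrast {self.contrast} not among {sorted(conditions)}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["subjects"] = [SubjectSpec(**s) for s in raw.get("subjects", [])]
        if raw.get("contrast") is not None:
            raw["contrast"] = tuple(raw["contrast"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str) -> None:
        raw = dataclasses.asdict(self)
        if raw.get("contrast") is not None:
            raw["contrast"] = list(raw["contrast"])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _prepare_signal(ts: RegionTimeSeries, cfg: RunConfig,
                    band: str | None) -> RegionTimeSeries:
    if cfg.resample_hz is not None and cfg.resample_hz < ts.sampling_rate:
        ts = prep.resample_timeseries(ts, cfg.resample_hz)
    if band is not None:
        ts = prep.hilbert_envelope(prep.bandpass(ts, prep.STANDARD_BANDS[band]))
    return ts


def run_pipeline(config: RunConfig) -> str:
    """Execute prep -> SDI -> surrogates -> group on every subject/condition.

    Writes per-subject SDI tables, significance labels, group counts and
    masks, the optional paired contrast, and the resolved config into
    ``config.out_dir``.  Returns the output directory.  All randomness
    derives from ``config.seed``; the per-subject cutoff C is logged.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    config.to_yaml(os.path.join(config.out_dir, "resolved_config.yaml"))
    signal_variants: list[str | None] = [None] + list(config.bands)
    master = np.random.SeedSequence(config.seed)
    subject_seeds = master.generate_state(len(config.subjects))

    region_ids: list[str] | None = None
    all_sdi: dict[tuple[str | None, str], dict[str, np.ndarray]] = {}
    all_sig: dict[tuple[str | None, str], list[surr.SignificanceMap]] = {}

    for s_idx, subject in enumerate(config.subjects):
        conn = load_connectome(
            subject.connectome, config.region_table, subject_id=subject.subject_id
        )
        if region_ids is None:
            region_ids = list(conn.region_ids)
        elif conn.region_ids != region_ids:
            raise ValueError(
                f"region order of {subject.subject_id} differs from the first subject"
            )
        spectrum = eigendecompose(normalized_laplacian(conn))
        for condition, ts_path in sorted(subject.timeseries.items()):
            raw = load_timeseries(ts_path, region_count=conn.n_regions)
            for band in signal_variants:
                ts = _prepare_signal(raw, config, band)
                sdi_map = gsp._sdi_from_spectrum(spectrum, ts)
                tag = band or "raw"
                logger.info(
                    "subject=%s condition=%s band=%s cutoff_C=%d",
                    subject.subject_id, condition, tag, sdi_map.cutoff_C,
                )
                stem = f"{subject.subject_id}_{condition}_{tag}"
                save_sdi_map(sdi_map, region_ids,
                             os.path.join(config.out_dir, f"sdi_{stem}.csv"))
                surrogate_set = surr.surrogate_sdi_set(
                    conn, ts, k=config.k_surrogates,
                    seed=int(subject_seeds[s_idx] % 2**31),
                    spectrum=spectrum,
                )
                sig = surr.individual_significance(sdi_map, surrogate_set)
                pd.DataFrame(
                    {"region": region_ids, "label": sig.labels}
                ).to_csv(os.path.join(config.out_dir, f"sig_{stem}.csv"), index=False)
                key = (band, condition)
                all_sdi.setdefault(key, {})[subject.subject_id] = sdi_map.sdi
                all_sig.setdefault(key, []).append(sig)
                if config.time_resolved:
                    tr = gsp.time_resolved_sdi(
                        conn, ts, config.window_seconds, spectrum=spectrum
                    )
                    save_time_resolved(
                        tr, region_ids,
                        os.path.join(config.out_dir, f"tr_sdi_{stem}.csv"),
                    )

    threshold = surr.binomial_group_threshold(
        len(config.subjects), config.p_success, config.alpha_group
    )
    for (band, condition), sig_maps in all_sig.items():
        tag = band or "raw"
        sdi_matrix = np.stack(list(all_sdi[(band, condition)].values()))
        group = surr.group_significance(sig_maps, threshold, empirical_sdi=sdi_matrix)
        pd.DataFrame(
            {
                "region": region_ids,
                "coupled_count": group.coupled_counts,
                "decoupled_count": group.decoupled_counts,
                "coupled_sig": group.coupled_mask,
                "decoupled_sig": group.decoupled_mask,
                "group_sdi": group.group_sdi,
            }
        ).to_csv(
            os.path.join(config.out_dir, f"group_{condition}_{tag}.csv"), index=False
        )

    if config.contrast is not None:
        cond_a, cond_b = config.contrast
        for band in signal_variants:
            tag = band or "raw"
            a = all_sdi.get((band, cond_a))
            b = all_sdi.get((band, cond_b))
            if not a or not b:
                continue
            shared = sorted(set(a) & set(b))
            contrast = stats.paired_contrast(
                np.stack([a[s] for s in shared]),
                np.stack([b[s] for s in shared]),
                alpha=config.alpha_contrast,
                contrast=(cond_a, cond_b),
            )
            pd.DataFrame(
                {
                    "region": region_ids,
                    "t": contrast.t_values,
                    "p": contrast.p_values,
                    "q": contrast.q_values,
                    "significant": contrast.mask,
                }
            ).to_csv(
                os.path.join(config.out_dir, f"contrast_{cond_a}_vs_{cond_b}_{tag}.csv"),
                index=False,
            )

    with open(os.path.join(config.out_dir, "run_summary.json"), "w") as fh:
        json.dump(
            {
                "n_subjects": len(config.subjects),
                "binomial_threshold": threshold,
                "k_surrogates": config.k_surrogates,
                "seed": config.seed,
            },
            fh,
            indent=2,
        )
    return config.out_dir
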
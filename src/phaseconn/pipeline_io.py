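"""Recording containers, readers/writers, preprocessing, segmentation and
the end-to-end pipeline.

Recordings are multichannel matrices (channels x samples) with 10-20
montage labels.  Supported on-disk formats: EDF (read, via mne), delimited
text matrices (read/write; first column = channel label), and MATLAB
containers as deposited with the study data (read, thin converter).

The default preprocessing is deliberately minimal and fully logged:
per-channel mean removal and high-pass drift removal below 0.5 Hz, with an
optional mains notch.  No re-referencing is applied.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import butter, iirnotch, filtfilt, sosfiltfilt

from . import dbi as _dbi
from . import group_stats as _gs
from . import surrogates as _sur
from . import timefreq as _tf

logger = logging.getLogger("phaseconn")

__all__ = [
    "STANDARD_1020",
    "Recording",
    "SegmentPlan",
    "PreprocessConfig",
    "read_recording",
    "write_recording",
    "save_cohort",
    "load_cohort",
    "preprocess",
    "plan_segments",
    "run_pipeline",
    "load_config",
]

#: The 19 probes of the standard 10-20 montage used for scalp EEG.
STANDARD_1020 = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz", "C3", "C4", "Cz",
    "T3", "T4", "T5", "T6", "P3", "P4", "Pz", "O1", "O2",
)

_ACCEPTED_RATES = (256.0, 500.0)


@dataclass
class Recording:
    """A multichannel recording: labels, sampling rate, channels x samples."""

    labels: list[str]
    fs: float
    data: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("number of labels does not match number of channels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels")
        if self.fs not in _ACCEPTED_RATES:
            warnings.warn(
                f"sampling rate {self.fs} Hz is not one of the study rates "
                f"{_ACCEPTED_RATES}; proceeding anyway",
                UserWarning,
                stacklevel=2,
            )
        unknown = [l for l in self.labels if l not in STANDARD_1020]
        if unknown:
            warnings.warn(
                f"labels not in the 10-20 montage (retained): {unknown}",
                UserWarning,
                stacklevel=2,
            )

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]


@dataclass(frozen=True)
class SegmentPlan:
    """How to cut analysis segments from a recording.

    mode 'sequential' — ``n_segments`` consecutive, non-overlapping
    segments from the start; 'central' — the middle ``length`` seconds;
    'explicit' — segments starting at the given ``starts`` (seconds),
    e.g. video-selected intervals.
    """

    length: float = 180.0
    mode: str = "sequential"
    n_segments: int = 5
    starts: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("segment length must be positive")
        if self.mode not in ("sequential", "central", "explicit"):
            raise ValueError("mode must be 'sequential', 'central' or 'explicit'")
        if self.mode == "explicit" and not self.starts:
            raise ValueError("explicit mode needs start times")


@dataclass(frozen=True)
class PreprocessConfig:
    demean: bool = True
    drift_cutoff: float | None = 0.5     # Hz; None disables
    notch: float | None = None           # 50.0 or 60.0, None disables

    @property
    def enabled(self) -> bool:
        return self.demean or self.drift_cutoff is not None or self.notch is not None


# ---------------------------------------------------------------- readers --

def read_recording(path, fmt: str | None = None, fs: float | None = None,
                   meta: dict | None = None) -> Recording:
    """Read a recording from EDF, delimited text, or a MATLAB container.

    Delimited matrices are channels x samples with the channel label in the
    first column (``fs`` required unless a ``# fs=...`` header is present).
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "edf":
        return _read_edf(path, meta)
    if fmt in ("tsv", "csv", "txt"):
        return _read_delimited(path, fs, meta)
    if fmt == "mat":
        return _read_mat(path, fs, meta)
    raise ValueError(f"unsupported format {fmt!r}")


def _read_edf(path: Path, meta: dict | None) -> Recording:
    import mne  # lazy: optional heavyweight dependency

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = [ch.split()[-1].strip(".").capitalize() if ch.lower().startswith("eeg")
              else ch for ch in raw.ch_names]
    try:
        data = raw.get_data(units="uV")  # undo mne's SI conversion for uV channels
    except (ValueError, TypeError):
        data = raw.get_data()
    return Recording(labels, float(raw.info["sfreq"]), data, meta or {})


def _read_delimited(path: Path, fs: float | None, meta: dict | None) -> Recording:
    header_fs = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first.lstrip("#").split():
            if tok.startswith("fs="):
                header_fs = float(tok[3:])
    fs = fs if fs is not None else header_fs
    if fs is None:
        raise ValueError("sampling rate not given and no '# fs=' header found")
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     float_precision="round_trip")
    if df.shape[1] == 1:  # comma-delimited variant
        df = pd.read_csv(path, sep=",", header=None, comment="#",
                         float_precision="round_trip")
    labels = df.iloc[:, 0].astype(str).tolist()
    data = df.iloc[:, 1:].to_numpy(dtype=float)
    return Recording(labels, float(fs), data, meta or {})


def _read_mat(path: Path, fs: float | None, meta: dict | None) -> Recording:
    """Thin converter for MATLAB containers (v7.3/HDF5 or classic)."""
    arrays: dict[str, np.ndarray] = {}
    try:
        from scipy.io import loadmat

        raw = loadmat(path)
        arrays = {k: np.asarray(v) for k, v in raw.items() if not k.startswith("__")}
    except NotImplementedError:  # v7.3: HDF5-backed
        import h5py

        with h5py.File(path, "r") as fh:
            fh.visititems(
                lambda name, obj: arrays.__setitem__(name, np.asarray(obj))
                if hasattr(obj, "shape") and np.asarray(obj).ndim == 2 else None
            )
    if not arrays:
        raise ValueError(f"no 2-D numeric array found in {path}")
    name, data = max(arrays.items(), key=lambda kv: kv[1].size)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] > data.shape[1]:  # stored samples x channels
        data = data.T
    if fs is None:
        raise ValueError("sampling rate must be supplied for .mat recordings")
    labels = list(STANDARD_1020[: data.shape[0]]) if data.shape[0] <= 19 else [
        f"ch{i}" for i in range(data.shape[0])
    ]
    logger.info("read %s: array %r, %d channels", path, name, data.shape[0])
    return Recording(labels, float(fs), data, meta or {})


def write_recording(path, rec: Recording) -> None:
    """Write a recording as a tab-delimited matrix with a '# fs=' header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs}\n")
        for label, row in zip(rec.labels, rec.data):
            fh.write(label + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def save_cohort(directory, recordings, metadata: pd.DataFrame) -> None:
    """Write per-subject delimited matrices plus a metadata table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(directory / f"{rec.meta['subject']}.tsv", rec)
    metadata.to_csv(directory / "metadata.csv", index=False)


def load_cohort(directory) -> tuple[list[Recording], pd.DataFrame]:
    directory = Path(directory)
    metadata = pd.read_csv(directory / "metadata.csv")
    recordings = []
    for row in metadata.itertuples():
        rec = read_recording(directory / f"{row.subject}.tsv")
        rec.meta.update({"subject": row.subject, "group": row.group})
        recordings.append(rec)
    return recordings, metadata


# ---------------------------------------------------------- preprocessing --

def preprocess(rec: Recording, config: PreprocessConfig | None = None) -> Recording:
    """Default preprocessing: demean, drift removal, optional notch.

    Every applied step is logged.  With everything disabled the data pass
    through unchanged (identity).
    """
    config = PreprocessConfig() if config is None else config
    if not config.enabled:
        return replace(rec, data=rec.data.copy(), meta=dict(rec.meta))
    data = rec.data.copy()
    if config.demean:
        data -= data.mean(axis=1, keepdims=True)
        logger.info("preprocess: removed per-channel mean")
    if config.drift_cutoff is not None:
        sos = butter(2, config.drift_cutoff, btype="highpass", fs=rec.fs, output="sos")
        data = sosfiltfilt(sos, data, axis=1)
        logger.info("preprocess: high-pass drift removal below %g Hz", config.drift_cutoff)
    if config.notch is not None:
        b, a = iirnotch(config.notch, Q=30.0, fs=rec.fs)
        data = filtfilt(b, a, data, axis=1)
        logger.info("preprocess: %g Hz notch", config.notch)
    return replace(rec, data=data, meta=dict(rec.meta))


def plan_segments(rec: Recording, plan: SegmentPlan) -> list[Recording]:
    """Cut a recording into analysis segments according to the plan."""
    n_seg_samples = int(round(plan.length * rec.fs))
    total = rec.data.shape[1]
    if plan.mode == "sequential":
        starts = [k * n_seg_samples for k in range(plan.n_segments)]
    elif plan.mode == "central":
        starts = [(total - n_seg_samples) // 2]
    else:
        starts = [int(round(s * rec.fs)) for s in plan.starts]
    out = []
    for idx, s in enumerate(starts):
        if s < 0 or s + n_seg_samples > total:
            raise ValueError(
                f"segment {idx} ({s / rec.fs:.1f}-{(s + n_seg_samples) / rec.fs:.1f} s) "
                f"exceeds the {rec.duration:.1f} s record"
            )
        meta = dict(rec.meta, segment=idx)
        out.append(Recording(list(rec.labels), rec.fs, rec.data[:, s : s + n_seg_samples], meta))
    return out


# -------------------------------------------------------------- pipeline --

_DEFAULT_CONFIG = {
    "band": [3.5, 12.0],
    "wavelet": {"central_frequency": 4.0, "voices_per_octave": 24,
                "fmin": 3.0, "fmax": 14.0},
    "segment": {"length": 180.0, "mode": "sequential", "n_segments": 5},
    "preprocess": {"demean": True, "drift_cutoff": 0.5, "notch": None},
    "pairs": [["Fp1", "Fp2"], ["F3", "Fp2"], ["Fp1", "F4"], ["F3", "F4"]],
    "dbi": {"enabled": False, "window": 3.0, "propagation_constant": 0.2,
            "basis_order": 2, "phase_fs": 40.0},
    "shuffles": 1000,
    "seed": 0,
}


def load_config(path) -> dict:
    """Read a structured-text (YAML) pipeline configuration."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(_DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: dict, recordings=None, metadata: pd.DataFrame | None = None,
                 out_dir=None):
    """Run the full connectivity pipeline on a cohort.

    read -> preprocess -> segment -> wavelet transform -> WPC +
    intersubject surrogates -> effective coherence [-> DBI -> coupling
    time] -> group statistics.  Returns a result dictionary; when
    ``out_dir`` is given, writes ``coherence.csv``, ``coupling_time.csv``
    (if DBI enabled), ``group_stats.json``, per-group heatmap matrices and
    ``manifest.json``.

    ``recordings``/``metadata`` may be passed directly (e.g. from
    :mod:`phaseconn.synthetic_data`); otherwise ``config['cohort_dir']`` is
    loaded from disk.
    """
    cfg = json.loads(json.dumps(_DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val

    if recordings is None:
        if "simulate" in cfg:
            from .synthetic_data import CohortSpec, generate_cohort

            sim = dict(cfg["simulate"])
            for key in ("channel_labels", "n_per_group", "group_names"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "coupled_pairs" in sim:
                sim["coupled_pairs"] = tuple(tuple(p) for p in sim["coupled_pairs"])
            cohort = generate_cohort(CohortSpec(**sim))
            recordings, metadata = cohort.recordings, cohort.metadata
        else:
            recordings, metadata = load_cohort(cfg["cohort_dir"])
    band = tuple(cfg["band"])
    pairs = [tuple(p) for p in cfg["pairs"]]
    wl = cfg["wavelet"]
    pre = PreprocessConfig(**cfg["preprocess"])
    seg_cfg = cfg["segment"]
    plan = SegmentPlan(length=seg_cfg["length"], mode=seg_cfg["mode"],
                       n_segments=seg_cfg.get("n_segments", 5),
                       starts=tuple(seg_cfg["starts"]) if seg_cfg.get("starts") else None)
    rng = np.random.default_rng(cfg["seed"])

    groups = sorted({r.meta["group"] for r in recordings})
    if len(groups) != 2:
        raise ValueError("pipeline expects exactly two groups")

    needed = sorted({ch for p in pairs for ch in p})
    # phase fields per group/segment/subject: {group: {segment: [ {label: PhaseField} ]}}
    fields: dict[str, dict[int, list[dict]]] = {g: {} for g in groups}
    subj_of: dict[str, dict[int, list[str]]] = {g: {} for g in groups}
    raw_segments: dict[str, dict[int, list[Recording]]] = {g: {} for g in groups}
    for rec in recordings:
        g = rec.meta["group"]
        clean = preprocess(rec, pre)
        for seg in plan_segments(clean, plan):
            idx = seg.meta["segment"]
            params = _tf.WaveletParams(fs=seg.fs, fmin=wl["fmin"], fmax=wl["fmax"],
                                       central_frequency=wl["central_frequency"],
                                       voices_per_octave=wl["voices_per_octave"])
            chan_fields = {}
            for ch in needed:
                rep = _tf.wavelet_transform(seg.channel(ch), params)
                chan_fields[ch] = _tf.extract_phase(rep)
            fields[g].setdefault(idx, []).append(chan_fields)
            subj_of[g].setdefault(idx, []).append(rec.meta["subject"])
            raw_segments[g].setdefault(idx, []).append(seg)

    # effective coherence per subject/segment/pair
    rows = []
    for g in groups:
        for idx, subjects in fields[g].items():
            for pair in pairs:
                pool = _sur.intersubject_pool(subjects, pair, group=g)
                actual = _sur.actual_spectra(subjects, pair)
                for subj, spec in zip(subj_of[g][idx], actual):
                    rows.append({
                        "subject": subj, "group": g, "segment": idx,
                        "pair": f"{pair[0]}-{pair[1]}",
                        "value": _sur.effective_coherence(spec, pool, band),
                    })
    coherence_table = pd.DataFrame(rows)

    # optional DBI -> coupling time
    coupling_table = None
    if cfg["dbi"]["enabled"]:
        dcfg = _dbi.DbiConfig(window=cfg["dbi"]["window"],
                              propagation_constant=cfg["dbi"]["propagation_constant"],
                              basis_order=cfg["dbi"]["basis_order"],
                              band=band, phase_fs=cfg["dbi"]["phase_fs"])
        rows = []
        for g in groups:
            for idx, segs in raw_segments[g].items():
                phases = []
                for seg in segs:
                    ph = {}
                    for ch in needed:
                        p = _dbi.extract_band_phase(seg.channel(ch), band, seg.fs)
                        ph[ch], pfs = _dbi.downsample_phase(p, seg.fs, dcfg.phase_fs)
                    phases.append((ph, pfs))
                for pair in pairs:
                    a_lbl, b_lbl = pair
                    per_subj = []
                    for ph, pfs in phases:
                        fits = _dbi.fit_windows(ph[a_lbl], ph[b_lbl], pfs, dcfg)
                        per_subj.append(_dbi.coupling_series(fits))
                    # intersubject surrogate coupling strengths (subsampled pairs)
                    null = []
                    n_s = len(phases)
                    for i in range(n_s):
                        for j in range(n_s):
                            if i == j:
                                continue
                            pa, pfa = phases[i]
                            pb, _ = phases[j]
                            nmin = min(pa[a_lbl].size, pb[b_lbl].size)
                            fits = _dbi.fit_windows(pa[a_lbl][:nmin], pb[b_lbl][:nmin],
                                                    pfa, dcfg)
                            s = _dbi.coupling_series(fits)
                            null.append(s.strength_a_to_b.mean())
                            null.append(s.strength_b_to_a.mean())
                    thr = _sur.coupling_threshold(np.asarray(null))
                    for subj, series in zip(subj_of[g][idx], per_subj):
                        for direction in ("a_to_b", "b_to_a"):
                            rows.append({
                                "subject": subj, "group": g, "segment": idx,
                                "pair": f"{a_lbl}-{b_lbl}", "direction": direction,
                                "value": series.coupling_time_pct(thr, direction),
                            })
        coupling_table = pd.DataFrame(rows)

    stats_out = {"wpc": _group_stats_block(coherence_table, groups, cfg, rng)}
    if coupling_table is not None and len(coupling_table):
        stats_out["dbi"] = _group_stats_block(coupling_table, groups, cfg, rng,
                                              by_direction=True)

    result = {
        "coherence": coherence_table,
        "coupling_time": coupling_table,
        "group_stats": stats_out,
        "heatmaps": _heatmaps(coherence_table, groups),
        "config": cfg,
    }
    if out_dir is not None:
        _write_outputs(result, out_dir, cfg)
    return result


def _group_stats_block(table, groups, cfg, rng, by_direction=False):
    out = {}
    keys = ["pair", "direction"] if by_direction else ["pair"]
    for key, sub in table.groupby(keys):
        name = key[0] if not by_direction else f"{key[0]}:{key[1]}"
        entry = {}
        for idx, seg_tab in sub.groupby("segment"):
            a = seg_tab.loc[seg_tab["group"] == groups[0], "value"]
            b = seg_tab.loc[seg_tab["group"] == groups[1], "value"]
            entry[f"segment_{idx}"] = {
                "p_ranksum": _gs.rank_sum(a, b),
                "cohens_d": _gs.cohens_d(a, b),
            }
        if sub["segment"].nunique() >= 2:
            entry["shuffled_pct_significant"] = _gs.shuffled_segment_test(
                sub, n_shuffles=cfg["shuffles"], seed=rng
            )
        if sub["segment"].nunique() >= 3:
            # repeated-measures consistency gate, per group
            for g in groups:
                blocks = (
                    sub[sub["group"] == g]
                    .pivot_table(index="subject", columns="segment", values="value")
                )
                entry[f"p_friedman_{g}"] = _gs.friedman_repeats(blocks)
        out[name] = entry
    return out


def _heatmaps(table, groups):
    """Probe x probe matrices of group-median values (symmetric for WPC)."""
    out = {}
    for g in groups:
        sub = table[table["group"] == g]
        med = sub.groupby("pair")["value"].median()
        chans = sorted({c for p in med.index for c in p.split("-")})
        mat = pd.DataFrame(np.nan, index=chans, columns=chans)
        for pair, v in med.items():
            a, b = pair.split("-")
            mat.loc[a, b] = mat.loc[b, a] = v
        out[g] = mat
    return out


def _write_outputs(result, out_dir, cfg) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result["coherence"].to_csv(out / "coherence.csv", index=False)
    if result["coupling_time"] is not None:
        result["coupling_time"].to_csv(out / "coupling_time.csv", index=False)
    with open(out / "group_stats.json", "w") as fh:
        json.dump(result["group_stats"], fh, indent=2, default=float)
    for g, mat in result["heatmaps"].items():
        mat.to_csv(out / f"heatmap_{g}.csv")
    manifest = {"config": cfg, "config_hash": _config_hash(cfg), "seed": cfg["seed"]}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
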
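"""Probe montage, region mapping and recording I/O.

The measurement layout is a 38-channel bilateral montage built from 18
source and 16 detector optodes at 30 mm separation, covering seven
cortical regions per hemisphere: prefrontal (PFC), dorsolateral
prefrontal (DLPFC), superior frontal (SFC), premotor (PMC), primary
motor (M1), primary somatosensory (S1) and occipital (OC) cortex.
Channel-to-region assignment is declarative — a TSV fixture shipped with
the package — so a user with digitized optode positions can substitute
their own table without touching any analysis code.

Because subjects differ in lesion side, group analyses are performed in
an ipsilesional (I) / contralesional (C) frame: :func:`remap_hemispheres`
relabels the anatomical left/right hemispheres per subject, yielding the
14 effective region labels (IPFC, CPFC, ..., IOC, COC).

Recordings are chromophore concentration-change series (ΔO2Hb / ΔHHb,
typically µM) sampled at 10 Hz, carrying resting / motor-training state
annotations and subject metadata.  Two on-disk formats are supported:

* a native TSV (one row per sample, one column per channel×chromophore)
  with a JSON sidecar holding sample rate, channel order, state
  intervals and subject metadata;
* SNIRF (HDF5), written and read directly through h5py using the
  processed-concentration data type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DataQualityError,
    DomainError,
    FormatError,
    MontageError,
    NirswaveError,
)

Side = Literal["left", "right"]

#: Canonical region names, one set per hemisphere.
REGIONS: tuple[str, ...] = ("PFC", "DLPFC", "SFC", "PMC", "M1", "S1", "OC")

#: Default minimum number of slow-oscillation cycles a state must contain
#: for phase analysis at the lower band edge to be meaningful.
MIN_CYCLES_DEFAULT = 5
F_MIN_HZ_DEFAULT = 0.01

_MONTAGE_RESOURCE = "montage_38ch.tsv"
_DEMOGRAPHICS_RESOURCE = "cohort_demographics.tsv"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject clinical metadata.

    ``lesion_side`` and ``hemiplegia_side`` are recorded independently
    (they are usually, but not necessarily, opposite).  ``mmt_grade`` is
    the manual muscle test grade, 0 (no contraction) to 5 (normal).
    """

    subject_id: str
    lesion_side: Side
    hemiplegia_side: Side
    mmt_grade: int
    etiology: str | None = None
    time_since_onset_months: float | None = None

    def __post_init__(self) -> None:
        if self.lesion_side not in ("left", "right"):
            raise DomainError(f"lesion_side must be left/right, got {self.lesion_side!r}")
        if self.hemiplegia_side not in ("left", "right"):
            raise DomainError(
                f"hemiplegia_side must be left/right, got {self.hemiplegia_side!r}"
            )
        if not 0 <= int(self.mmt_grade) <= 5:
            raise DomainError(f"mmt_grade must be in [0, 5], got {self.mmt_grade}")


@dataclass(frozen=True)
class ProbeLayout:
    """Optode layout: labeled sources/detectors and the channel pairing."""

    sources: tuple[str, ...]
    detectors: tuple[str, ...]
    channels: tuple[tuple[str, str], ...]
    channel_names: tuple[str, ...]
    separation_mm: float = 30.0

    def __post_init__(self) -> None:
        src, det = set(self.sources), set(self.detectors)
        for s, d in self.channels:
            if s not in src:
                raise MontageError(f"channel references unknown source {s!r}")
            if d not in det:
                raise MontageError(f"channel references unknown detector {d!r}")
        if len(self.channel_names) != len(self.channels):
            raise MontageError("channel_names and channels length mismatch")

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass(frozen=True)
class RegionMap:
    """Channel → (hemisphere, region) assignment, optionally lesion-aware.

    When ``lesion_side`` is set, :meth:`effective` translates anatomical
    hemispheres into the ipsilesional/contralesional frame: channels on
    the lesioned hemisphere get an ``I`` prefix, the others ``C``.
    """

    assignments: dict[str, tuple[Side, str]]
    lesion_side: Side | None = None

    def __post_init__(self) -> None:
        per_hemi: dict[Side, set[str]] = {"left": set(), "right": set()}
        for ch, (hemi, region) in self.assignments.items():
            if hemi not in ("left", "right"):
                raise MontageError(f"{ch}: hemisphere must be left/right, got {hemi!r}")
            if region not in REGIONS:
                raise MontageError(f"{ch}: unknown region {region!r}")
            per_hemi[hemi].add(region)
        if per_hemi["left"] != set(REGIONS) or per_hemi["right"] != set(REGIONS):
            raise MontageError("each region must appear on both hemispheres")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.assignments)

    def effective(self, channel: str) -> str:
        """Effective region label for a channel, e.g. ``IM1`` or ``CSFC``."""
        if self.lesion_side is None:
            raise MontageError("effective labels require a lesion side; call remap_hemispheres")
        hemi, region = self.assignments[channel]
        prefix = "I" if hemi == self.lesion_side else "C"
        return prefix + region

    @property
    def effective_assignments(self) -> dict[str, str]:
        return {ch: self.effective(ch) for ch in self.assignments}

    @property
    def effective_regions(self) -> tuple[str, ...]:
        """The 14 effective region labels in canonical order (I then C)."""
        return tuple(p + r for p in ("I", "C") for r in REGIONS)

    def channels_in(self, effective_region: str) -> tuple[str, ...]:
        return tuple(
            ch for ch in self.assignments if self.effective(ch) == effective_region
        )


@dataclass(frozen=True)
class StateInterval:
    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise FormatError(
                f"state {self.label!r}: end ({self.end_s}) must exceed start ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Recording:
    """Multichannel ΔO2Hb/ΔHHb concentration series with annotations."""

    sample_rate_hz: float
    o2hb: np.ndarray            # (n_channels, n_samples)
    hhb: np.ndarray             # (n_channels, n_samples)
    channel_names: tuple[str, ...]
    state_intervals: tuple[StateInterval, ...]
    meta: SubjectMeta

    def __post_init__(self) -> None:
        self.o2hb = np.asarray(self.o2hb, dtype=float)
        self.hhb = np.asarray(self.hhb, dtype=float)
        if self.o2hb.shape != self.hhb.shape:
            raise FormatError(
                f"o2hb {self.o2hb.shape} and hhb {self.hhb.shape} shapes differ"
            )
        if self.o2hb.ndim != 2 or self.o2hb.shape[0] != len(self.channel_names):
            raise FormatError(
                f"expected (n_channels={len(self.channel_names)}, n_samples) arrays, "
                f"got {self.o2hb.shape}"
            )
        dur = self.duration_s
        ivs = sorted(self.state_intervals, key=lambda s: s.start_s)
        for iv in ivs:
            if iv.start_s < 0 or iv.end_s > dur + 0.5 / self.sample_rate_hz:
                raise FormatError(
                    f"state {iv.label!r} [{iv.start_s}, {iv.end_s}] s outside recording "
                    f"of {dur:.1f} s"
                )
        for a, b in zip(ivs, ivs[1:]):
            if b.start_s < a.end_s:
                raise FormatError(f"state intervals {a.label!r} and {b.label!r} overlap")

    @property
    def n_samples(self) -> int:
        return self.o2hb.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def series(self, chromophore: str) -> np.ndarray:
        if chromophore == "o2hb":
            return self.o2hb
        if chromophore == "hhb":
            return self.hhb
        raise DomainError(f"chromophore must be 'o2hb' or 'hhb', got {chromophore!r}")

    def state_slice(self, label: str) -> slice:
        """Sample slice of the (single) state interval with the given label."""
        matches = [iv for iv in self.state_intervals if iv.label == label]
        if not matches:
            raise DomainError(f"no state interval labeled {label!r}")
        iv = matches[0]
        fs = self.sample_rate_hz
        return slice(int(round(iv.start_s * fs)), int(round(iv.end_s * fs)))

    @property
    def state_labels(self) -> tuple[str, ...]:
        return tuple(iv.label for iv in self.state_intervals)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("nirswave").joinpath("data", name)))


def load_montage(path: str | Path | None = None) -> tuple[ProbeLayout, RegionMap]:
    """Load the probe layout and region assignment table.

    Without ``path`` the packaged 38-channel bilateral fixture is used.
    The table must have columns channel/source/detector/hemisphere/region.
    """
    p = Path(path) if path is not None else _data_path(_MONTAGE_RESOURCE)
    table = pd.read_csv(p, sep="\t")
    required = {"channel", "source", "detector", "hemisphere", "region"}
    if not required.issubset(table.columns):
        raise FormatError(f"montage table missing columns {required - set(table.columns)}")
    sources = tuple(dict.fromkeys(table["source"]))
    detectors = tuple(dict.fromkeys(table["detector"]))
    layout = ProbeLayout(
        sources=sources,
        detectors=detectors,
        channels=tuple(zip(table["source"], table["detector"])),
        channel_names=tuple(table["channel"]),
    )
    assignments = {
        row.channel: (row.hemisphere, row.region) for row in table.itertuples()
    }
    return layout, RegionMap(assignments=assignments)


def load_demographics(path: str | Path | None = None) -> pd.DataFrame:
    """Load the study-cohort characteristics table (one row per subject)."""
    p = Path(path) if path is not None else _data_path(_DEMOGRAPHICS_RESOURCE)
    df = pd.read_csv(p, sep="\t")
    df["group"] = df["mmt_grade"].map(assign_group)
    return df


def subject_meta_from_row(row) -> SubjectMeta:
    return SubjectMeta(
        subject_id=str(row["subject_id"]),
        lesion_side=row["lesion_side"],
        hemiplegia_side=row["hemiplegia_side"],
        mmt_grade=int(row["mmt_grade"]),
        etiology=row.get("etiology"),
        time_since_onset_months=float(row["time_since_onset_months"])
        if "time_since_onset_months" in row
        else None,
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def assign_group(mmt_grade: int) -> str:
    """Map a manual-muscle-test grade to the impairment group.

    Grades 0–1 → ``severe``, 2–3 → ``moderate``, 4–5 → ``mild``.
    """
    g = int(mmt_grade)
    if not 0 <= g <= 5:
        raise DomainError(f"mmt_grade must be in [0, 5], got {mmt_grade}")
    if g <= 1:
        return "severe"
    if g <= 3:
        return "moderate"
    return "mild"


def remap_hemispheres(region_map: RegionMap, lesion_side: Side) -> RegionMap:
    """Return a copy of ``region_map`` viewed from the given lesion side."""
    if lesion_side not in ("left", "right"):
        raise DomainError(f"lesion_side must be left/right, got {lesion_side!r}")
    return replace(region_map, lesion_side=lesion_side)


def validate_duration(
    rec: Recording,
    f_min_hz: float = F_MIN_HZ_DEFAULT,
    min_cycles: int = MIN_CYCLES_DEFAULT,
) -> dict[str, bool]:
    """Check that each state contains enough slow-oscillation cycles.

    A state passes iff ``duration × f_min_hz ≥ min_cycles``; with the
    defaults a state must span at least five 0.01 Hz periods (500 s) for
    phase analysis at the band's lower edge to be considered valid.
    """
    if f_min_hz <= 0:
        raise DomainError("f_min_hz must be positive")
    report: dict[str, bool] = {}
    for iv in rec.state_intervals:
        if iv.duration_s <= 0:
            raise DomainError(f"state {iv.label!r} has non-positive duration")
        report[iv.label] = iv.duration_s * f_min_hz >= min_cycles
    return report


# ---------------------------------------------------------------------------
# native TSV + JSON sidecar format
# ---------------------------------------------------------------------------

_SIDECAR_REQUIRED = ("sample_rate_hz", "channels", "state_intervals", "subject")


def save_recording_tsv(rec: Recording, path: str | Path) -> Path:
    """Write ``<path>.tsv`` (samples × channel·chromophore) and ``<path>.json``."""
    path = Path(path)
    if path.suffix == ".tsv":
        path = path.with_suffix("")
    cols: dict[str, np.ndarray] = {}
    for i, ch in enumerate(rec.channel_names):
        cols[f"{ch}_O2Hb"] = rec.o2hb[i]
        cols[f"{ch}_HHb"] = rec.hhb[i]
    pd.DataFrame(cols).to_csv(path.with_suffix(".tsv"), sep="\t", index=False,
                              float_format="%.6g")
    sidecar = {
        "sample_rate_hz": rec.sample_rate_hz,
        "channels": list(rec.channel_names),
        "state_intervals": [
            {"label": iv.label, "start_s": iv.start_s, "end_s": iv.end_s}
            for iv in rec.state_intervals
        ],
        "subject": {
            "subject_id": rec.meta.subject_id,
            "lesion_side": rec.meta.lesion_side,
            "hemiplegia_side": rec.meta.hemiplegia_side,
            "mmt_grade": rec.meta.mmt_grade,
            "etiology": rec.meta.etiology,
            "time_since_onset_months": rec.meta.time_since_onset_months,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".tsv")


def _check_nan_runs(arr: np.ndarray, max_run: int, what: str) -> None:
    bad = ~np.isfinite(arr)
    for i, row in enumerate(bad):
        if not row.any():
            continue
        # run-length encode the NaN indicator
        edges = np.flatnonzero(np.diff(np.concatenate(([0], row.view(np.int8), [0]))))
        runs = edges[1::2] - edges[0::2]
        if runs.size and runs.max() > max_run:
            raise DataQualityError(
                f"{what} channel {i}: NaN run of {int(runs.max())} samples exceeds "
                f"limit {max_run}"
            )


def load_recording_tsv(
    path: str | Path,
    montage: ProbeLayout | None = None,
    max_nan_run_s: float = 1.0,
) -> Recording:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in _SIDECAR_REQUIRED:
        if key not in sidecar:
            raise FormatError(f"sidecar missing required field {key!r}")
    channels = tuple(sidecar["channels"])
    if montage is None:
        montage, _ = load_montage()
    if len(channels) != montage.n_channels or tuple(channels) != montage.channel_names:
        raise MontageError(
            f"sidecar channels do not match the {montage.n_channels}-channel montage"
        )
    table = pd.read_csv(path, sep="\t")
    try:
        o2hb = np.stack([table[f"{ch}_O2Hb"].to_numpy() for ch in channels])
        hhb = np.stack([table[f"{ch}_HHb"].to_numpy() for ch in channels])
    except KeyError as exc:
        raise FormatError(f"TSV missing expected column: {exc}") from exc
    fs = float(sidecar["sample_rate_hz"])
    max_run = max(1, int(round(max_nan_run_s * fs)))
    _check_nan_runs(o2hb, max_run, "O2Hb")
    _check_nan_runs(hhb, max_run, "HHb")
    sub = sidecar["subject"]
    try:
        intervals = tuple(
            StateInterval(iv["label"], float(iv["start_s"]), float(iv["end_s"]))
            for iv in sidecar["state_intervals"]
        )
        meta = SubjectMeta(
            subject_id=sub["subject_id"],
            lesion_side=sub["lesion_side"],
            hemiplegia_side=sub["hemiplegia_side"],
            mmt_grade=int(sub["mmt_grade"]),
            etiology=sub.get("etiology"),
            time_since_onset_months=sub.get("time_since_onset_months"),
        )
    except KeyError as exc:
        raise FormatError(f"sidecar missing field {exc}") from exc
    return Recording(
        sample_rate_hz=fs,
        o2hb=o2hb,
        hhb=hhb,
        channel_names=channels,
        state_intervals=intervals,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# SNIRF (HDF5) format
# ---------------------------------------------------------------------------

_HB_LABELS = {"o2hb": "HbO", "hhb": "HbR"}
_PROCESSED_DATA_TYPE = 99999  # SNIRF code for processed time series


def save_recording_snirf(rec: Recording, path: str | Path,
                         layout: ProbeLayout | None = None) -> Path:
    """Write the recording as a SNIRF v1.0 file (processed Hb concentrations)."""
    import h5py

    if layout is None:
        layout, _ = load_montage()
    path = Path(path)
    src_index = {s: i + 1 for i, s in enumerate(layout.sources)}
    det_index = {d: i + 1 for i, d in enumerate(layout.detectors)}
    n = rec.n_samples
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.meta.subject_id)
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("LesionSide", data=rec.meta.lesion_side)
        meta.create_dataset("HemiplegiaSide", data=rec.meta.hemiplegia_side)
        meta.create_dataset("MMTGrade", data=str(rec.meta.mmt_grade))
        if rec.meta.etiology is not None:
            meta.create_dataset("Etiology", data=str(rec.meta.etiology))
        if rec.meta.time_since_onset_months is not None:
            meta.create_dataset(
                "TimeSinceOnsetMonths", data=str(rec.meta.time_since_onset_months)
            )
        data = nirs.create_group("data1")
        series = np.empty((n, 2 * len(rec.channel_names)))
        col = 0
        for chrom in ("o2hb", "hhb"):
            arr = rec.series(chrom)
            for i_ch, (s, d) in enumerate(layout.channels):
                series[:, col] = arr[i_ch]
                ml = data.create_group(f"measurementList{col + 1}")
                ml.create_dataset("sourceIndex", data=src_index[s], dtype="i4")
                ml.create_dataset("detectorIndex", data=det_index[d], dtype="i4")
                ml.create_dataset("wavelengthIndex", data=1, dtype="i4")
                ml.create_dataset("dataType", data=_PROCESSED_DATA_TYPE, dtype="i4")
                ml.create_dataset("dataTypeLabel", data=_HB_LABELS[chrom])
                ml.create_dataset("dataTypeIndex", data=1, dtype="i4")
                col += 1
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset(
            "time", data=np.arange(n, dtype=float) / rec.sample_rate_hz
        )
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array([740.0, 850.0]))
        probe.create_dataset("sourceLabels", data=np.array(layout.sources, dtype="S"))
        probe.create_dataset("detectorLabels", data=np.array(layout.detectors, dtype="S"))
        for k, iv in enumerate(rec.state_intervals, start=1):
            stim = nirs.create_group(f"stim{k}")
            stim.create_dataset("name", data=iv.label)
            stim.create_dataset(
                "data", data=np.array([[iv.start_s, iv.duration_s, 1.0]])
            )
    return path


def _h5_str(value) -> str:
    v = value[()]
    if isinstance(v, bytes):
        return v.decode()
    return str(v)


def load_recording_snirf(path: str | Path,
                         layout: ProbeLayout | None = None) -> Recording:
    import h5py

    if layout is None:
        layout, _ = load_montage()
    path = Path(path)
    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        meta = nirs["metaDataTags"]
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        if time.size >= 2:
            fs = 1.0 / float(time[1] - time[0])
        else:
            raise FormatError("SNIRF time dataset too short to infer sample rate")
        src_pair = {i + 1: s for i, s in enumerate(layout.sources)}
        det_pair = {i + 1: d for i, d in enumerate(layout.detectors)}
        pair_to_row = {pair: i for i, pair in enumerate(layout.channels)}
        n = series.shape[0]
        o2hb = np.full((layout.n_channels, n), np.nan)
        hhb = np.full((layout.n_channels, n), np.nan)
        ml_names = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        if len(ml_names) != series.shape[1]:
            raise FormatError(
                f"SNIRF has {series.shape[1]} data columns but {len(ml_names)} "
                "measurementList entries"
            )
        for col, name in enumerate(ml_names):
            ml = data[name]
            pair = (
                src_pair[int(ml["sourceIndex"][()])],
                det_pair[int(ml["detectorIndex"][()])],
            )
            if pair not in pair_to_row:
                raise MontageError(f"SNIRF channel {pair} not in montage")
            label = _h5_str(ml["dataTypeLabel"])
            target = o2hb if label == "HbO" else hhb if label == "HbR" else None
            if target is None:
                raise FormatError(f"unsupported dataTypeLabel {label!r}")
            target[pair_to_row[pair]] = series[:, col]
        if np.isnan(o2hb).any() or np.isnan(hhb).any():
            raise MontageError("SNIRF file does not cover all montage channels")
        intervals = []
        for k in sorted(k for k in nirs.keys() if k.startswith("stim")):
            stim = nirs[k]
            label = _h5_str(stim["name"])
            onset, duration = np.asarray(stim["data"])[0][:2]
            intervals.append(StateInterval(label, float(onset), float(onset + duration)))
        submeta = SubjectMeta(
            subject_id=_h5_str(meta["SubjectID"]),
            lesion_side=_h5_str(meta["LesionSide"]),
            hemiplegia_side=_h5_str(meta["HemiplegiaSide"]),
            mmt_grade=int(_h5_str(meta["MMTGrade"])),
            etiology=_h5_str(meta["Etiology"]) if "Etiology" in meta else None,
            time_since_onset_months=float(_h5_str(meta["TimeSinceOnsetMonths"]))
            if "TimeSinceOnsetMonths" in meta
            else None,
        )
    return Recording(
        sample_rate_hz=fs,
        o2hb=o2hb,
        hhb=hhb,
        channel_names=layout.channel_names,
        state_intervals=tuple(intervals),
        meta=submeta,
    )


def load_recording(path: str | Path, format: str = "tsv", **kwargs) -> Recording:
    """Load a recording from the native TSV+JSON format or from SNIRF."""
    if format == "tsv":
        return load_recording_tsv(path, **kwargs)
    if format == "snirf":
        return load_recording_snirf(path, **kwargs)
    raise DomainError(f"format must be 'tsv' or 'snirf', got {format!r}")


def save_recording(rec: Recording, path: str | Path, format: str = "tsv", **kwargs) -> Path:
    """Save a recording in the native TSV+JSON format or as SNIRF."""
    if format == "tsv":
        return save_recording_tsv(rec, path, **kwargs)
    if format == "snirf":
        return save_recording_snirf(rec, path, **kwargs)
    raise DomainError(f"format must be 'tsv' or 'snirf', got {format!r}")
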
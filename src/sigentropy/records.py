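"""Domain types for online-signature recordings and cohorts, plus file I/O.

A signature captured on a digitizing tablet is a multi-channel time series:
pen position ``x``, ``y``, pen pressure ``p`` (0 while the pen is in the air),
and the two pen inclination angles, azimuth ``Az`` and altitude ``Alt``.
Signatures are exchanged on disk in an SVC2004-style plain-text dialect
(sample-count header, then one sample per line:
``x y time button azimuth altitude pressure``); cohort metadata travels in a
CSV with one row per subject.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

CHANNEL_NAMES = ("x", "y", "p", "Az", "Alt")
GROUPS = ("AD", "HC")
STYLES = ("stylized", "mixed", "text-based")


class SignatureDataError(ValueError):
    """Raised on malformed signature files or invalid domain objects."""


@dataclass
class RawChannel:
    """One raw temporal function u(1..N) of a signature.

    ``x``/``y`` are in tablet length units, ``p`` in device pressure units
    (>= 0, with p = 0 marking a pen-up sample), ``Az``/``Alt`` in degrees.
    """

    name: str
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in CHANNEL_NAMES:
            raise SignatureDataError(f"unknown channel name {self.name!r}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise SignatureDataError(
                f"channel {self.name}: need a 1-D series with N >= 2 samples"
            )
        if not np.all(np.isfinite(self.samples)):
            raise SignatureDataError(f"channel {self.name}: non-finite samples")
        if self.name == "p" and np.any(self.samples < 0):
            raise SignatureDataError("pressure samples must be >= 0")

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass
class SignatureRecord:
    """One signature instance: five equal-length raw channels."""

    subject_id: str
    instance: int
    channels: dict[str, RawChannel]
    sampling_rate: float = 125.0

    def __post_init__(self) -> None:
        if self.instance not in (1, 2):
            raise SignatureDataError("instance must be 1 or 2")
        if self.sampling_rate <= 0:
            raise SignatureDataError("sampling_rate must be > 0")
        if set(self.channels) != set(CHANNEL_NAMES):
            raise SignatureDataError(
                f"expected exactly the channels {CHANNEL_NAMES}, "
                f"got {sorted(self.channels)}"
            )
        lengths = {len(ch) for ch in self.channels.values()}
        if len(lengths) != 1:
            raise SignatureDataError("all channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.channels["x"])

    @property
    def pen_up_fraction(self) -> float:
        """Fraction of samples with zero pressure (pen in the air)."""
        p = self.channels["p"].samples
        return float(np.mean(p == 0))

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name].samples


@dataclass
class SubjectRecord:
    """One participant with metadata and exactly two signatures."""

    subject_id: str
    group: str
    age: float
    sex: str
    mmse: int
    handedness: str
    style: str
    signatures: list[SignatureRecord]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SignatureDataError(f"unknown group label {self.group!r}")
        if self.sex not in ("M", "F"):
            raise SignatureDataError(f"unknown sex {self.sex!r}")
        if not 0 <= self.mmse <= 30:
            raise SignatureDataError(f"MMSE out of 0-30: {self.mmse}")
        if self.handedness not in ("L", "R"):
            raise SignatureDataError(f"unknown handedness {self.handedness!r}")
        if self.style not in STYLES:
            raise SignatureDataError(f"unknown style {self.style!r}")
        if len(self.signatures) != 2 or {s.instance for s in self.signatures} != {1, 2}:
            raise SignatureDataError(
                "a subject needs exactly two signatures with instances {1, 2}"
            )
        for sig in self.signatures:
            if sig.subject_id != self.subject_id:
                raise SignatureDataError("signature subject_id mismatch")

    def signature(self, instance: int) -> SignatureRecord:
        for sig in self.signatures:
            if sig.instance == instance:
                return sig
        raise KeyError(instance)


@dataclass
class Cohort:
    """A set of subjects plus free-text provenance (e.g. simulator config)."""

    subjects: list[SubjectRecord]
    provenance: str = ""
    early_stage: bool = True

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise SignatureDataError("duplicate subject_id in cohort")
        if self.early_stage:
            for s in self.subjects:
                if s.group == "AD" and s.mmse <= 20:
                    raise SignatureDataError(
                        f"early-stage cohort requires MMSE > 20 for AD "
                        f"(subject {s.subject_id}: {s.mmse})"
                    )

    def __len__(self) -> int:
        return len(self.subjects)

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]

    @property
    def signatures(self) -> list[SignatureRecord]:
        return [sig for s in self.subjects for sig in s.signatures]


# ---------------------------------------------------------------------------
# SVC-dialect signature files
# ---------------------------------------------------------------------------

def _fmt(value: float) -> str:
    # repr round-trips float64 exactly; strip the trailing ".0" for integers
    # so integer-valued device readings look like integers on disk.
    if value == int(value) and abs(value) < 1e15:
        return str(int(value))
    return repr(float(value))


def read_signature_file(
    path: str | Path,
    dialect: str = "svc",
    subject_id: str | None = None,
    instance: int | None = None,
    sampling_rate: float = 125.0,
) -> SignatureRecord:
    """Read an SVC-style signature file.

    Each data line holds ``x y time button azimuth altitude pressure``.
    The button column is checked for consistency (button 0 should coincide
    with pressure 0) but pressure is authoritative for pen-up detection.
    Subject id and instance default to parsing the ``<subject>_<instance>``
    file-name convention.
    """
    if dialect != "svc":
        raise SignatureDataError(f"unknown dialect {dialect!r}")
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise SignatureDataError(f"{path}: empty file")
    try:
        n_declared = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise SignatureDataError(f"{path}: malformed count header") from exc
    rows = [ln.split() for ln in lines[1:] if ln.strip()]
    if len(rows) != n_declared:
        raise SignatureDataError(
            f"{path}: sample count mismatch (header {n_declared}, "
            f"{len(rows)} data rows)"
        )
    if n_declared < 2:
        raise SignatureDataError(f"{path}: need N >= 2 samples")
    if any(len(r) != 7 for r in rows):
        raise SignatureDataError(f"{path}: ragged line (expected 7 fields)")
    try:
        data = np.array([[float(v) for v in r] for r in rows])
    except ValueError as exc:
        raise SignatureDataError(f"{path}: non-numeric field") from exc

    if subject_id is None or instance is None:
        stem = path.stem
        if "_" in stem:
            sid, _, inst = stem.rpartition("_")
        else:
            sid, inst = stem, "1"
        subject_id = subject_id or sid
        if instance is None:
            try:
                instance = int(inst)
            except ValueError:
                instance = 1

    x, y, _time, button, az, alt, p = data.T
    if np.any((button == 0) != (p == 0)):
        raise SignatureDataError(
            f"{path}: button column inconsistent with pressure pen-up marks"
        )
    channels = {
        "x": RawChannel("x", x),
        "y": RawChannel("y", y),
        "p": RawChannel("p", p),
        "Az": RawChannel("Az", az),
        "Alt": RawChannel("Alt", alt),
    }
    return SignatureRecord(subject_id, instance, channels, sampling_rate)


def write_signature_file(
    signature: SignatureRecord, path: str | Path, dialect: str = "svc"
) -> None:
    """Write a signature in the SVC-style dialect read by
    :func:`read_signature_file`; the numeric round-trip is exact."""
    if dialect != "svc":
        raise SignatureDataError(f"unknown dialect {dialect!r}")
    path = Path(path)
    n = signature.n_samples
    dt_ms = 1000.0 / signature.sampling_rate
    x = signature.channel("x")
    y = signature.channel("y")
    p = signature.channel("p")
    az = signature.channel("Az")
    alt = signature.channel("Alt")
    out = [str(n)]
    for i in range(n):
        button = 0 if p[i] == 0 else 1
        out.append(
            " ".join(
                (
                    _fmt(x[i]),
                    _fmt(y[i]),
                    _fmt(round(i * dt_ms)),
                    str(button),
                    _fmt(az[i]),
                    _fmt(alt[i]),
                    _fmt(p[i]),
                )
            )
        )
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Cohort directory I/O
# ---------------------------------------------------------------------------

_METADATA_COLUMNS = ["subject_id", "group", "age", "sex", "mmse", "handedness", "style"]


def read_cohort(
    dirpath: str | Path,
    metadata_csv: str | Path | None = None,
    early_stage: bool = True,
) -> Cohort:
    """Load a cohort from a directory of ``<subject>_<1|2>.svc`` files plus a
    metadata CSV (columns subject_id, group, age, sex, mmse, handedness,
    style)."""
    dirpath = Path(dirpath)
    metadata_csv = Path(metadata_csv) if metadata_csv else dirpath / "metadata.csv"
    if not metadata_csv.exists():
        raise SignatureDataError(f"missing metadata file {metadata_csv}")
    subjects: list[SubjectRecord] = []
    seen: set[str] = set()
    with open(metadata_csv, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_METADATA_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise SignatureDataError(f"metadata missing columns: {sorted(missing)}")
        for row in reader:
            sid = row["subject_id"]
            if sid in seen:
                raise SignatureDataError(f"duplicate subject_id {sid!r}")
            seen.add(sid)
            sigs = []
            for inst in (1, 2):
                f = dirpath / f"{sid}_{inst}.svc"
                if not f.exists():
                    raise SignatureDataError(f"missing signature file {f}")
                sigs.append(read_signature_file(f, subject_id=sid, instance=inst))
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    group=row["group"],
                    age=float(row["age"]),
                    sex=row["sex"],
                    mmse=int(row["mmse"]),
                    handedness=row["handedness"],
                    style=row["style"],
                    signatures=sigs,
                )
            )
    return Cohort(subjects, provenance=f"read from {dirpath}", early_stage=early_stage)


def write_cohort(cohort: Cohort, dirpath: str | Path) -> None:
    """Write every signature as an SVC file plus ``metadata.csv``."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    with open(dirpath / "metadata.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_METADATA_COLUMNS)
        for s in cohort.subjects:
            writer.writerow(
                [s.subject_id, s.group, _fmt(s.age), s.sex, s.mmse, s.handedness, s.style]
            )
    for sig in cohort.signatures:
        write_signature_file(sig, dirpath / f"{sig.subject_id}_{sig.instance}.svc")
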
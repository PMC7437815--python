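"""Data model and on-disk bundle format for home-cage LFP recording sessions.

A *session bundle* is a directory holding one 60-min (by default) multi-site
hippocampal recording:

* ``signals.h5`` — HDF5 container with dataset ``lfp_uv`` (site x sample,
  float32, microvolts),
* ``meta.json`` — sample rate, electrode-site table, and mouse metadata,
* ``position.csv`` — 30 Hz video tracking (columns ``t_s,x_cm,y_cm``).

Times are seconds from session start, positions centimetres, and all
intervals throughout the package are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "Genotype",
    "AgeGroup",
    "ElectrodeSite",
    "LFPSession",
    "CohortManifest",
    "read_session_bundle",
    "write_session_bundle",
    "validate_session",
    "convert_crcns_hc26",
]


class Region(str, Enum):
    """Anatomical label of an electrode site."""

    CA1_PYR = "CA1_PYR"
    CA1_SR = "CA1_SR"
    CA3 = "CA3"
    DG = "DG"
    CORPUS_CALLOSUM = "CORPUS_CALLOSUM"
    OUT = "OUT"


class Genotype(str, Enum):
    E3 = "E3"
    E4 = "E4"


class AgeGroup(str, Enum):
    YOUNG = "YOUNG"
    MIDDLE = "MIDDLE"
    OLD = "OLD"


@dataclass(frozen=True)
class ElectrodeSite:
    site_id: str
    shank_index: int
    depth_index: int
    region: Region
    usable: bool = True


@dataclass
class LFPSession:
    """One multi-site recording with position tracking.

    ``signals`` is a (n_sites, n_samples) array in microvolts; ``position``
    is a (n_frames, 3) array with columns (t_s, x_cm, y_cm) at ~30 Hz.
    """

    mouse_id: str
    genotype: Genotype
    age_group: AgeGroup
    session_index: int
    sample_rate: float
    signals: np.ndarray
    sites: list[ElectrodeSite]
    position: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def site_index(self, site_id: str) -> int:
        for i, s in enumerate(self.sites):
            if s.site_id == site_id:
                return i
        raise KeyError(f"no site {site_id!r} in session {self.mouse_id}/{self.session_index}")

    def sites_in_region(self, region: Region) -> list[ElectrodeSite]:
        return [s for s in self.sites if s.region == region and s.usable]


@dataclass
class CohortManifest:
    """Index of a cohort: which mice, which session bundles, which behavior files."""

    cohort_label: str  # "SCREEN" or "REPLICATION"
    mice: list[dict] = field(default_factory=list)  # {mouse_id, genotype, sessions: [paths]}
    behavior_paths: dict = field(default_factory=dict)  # task -> path

    def validate(self, root: Path | None = None) -> list[str]:
        problems: list[str] = []
        ids = [m["mouse_id"] for m in self.mice]
        if len(ids) != len(set(ids)):
            problems.append("duplicate mouse_id in manifest")
        base = Path(root) if root is not None else Path(".")
        for m in self.mice:
            for p in m.get("sessions", []):
                if not (base / p).exists():
                    problems.append(f"missing session bundle: {p}")
        for task, p in self.behavior_paths.items():
            if not (base / p).exists():
                problems.append(f"missing behavior file for {task}: {p}")
        return problems


def validate_session(session: LFPSession) -> list[str]:
    """Return a list of invariant violations (empty list = valid).

    Pure and deterministic; never raises for content problems.
    """
    problems: list[str] = []
    sig = np.asarray(session.signals)
    if sig.ndim != 2:
        problems.append(f"signals must be 2-D (site x sample), got ndim={sig.ndim}")
        return problems
    if sig.shape[0] != len(session.sites):
        problems.append(
            f"site count mismatch: {sig.shape[0]} signal rows vs {len(session.sites)} sites"
        )
    if session.sample_rate < 1000:
        problems.append(f"sample_rate {session.sample_rate} Hz < 1000 Hz")
    ids = [s.site_id for s in session.sites]
    if len(ids) != len(set(ids)):
        problems.append("site_id values are not unique")
    pos = np.asarray(session.position, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        problems.append("position must be (n, 3): t_s, x_cm, y_cm")
        return problems
    t = pos[:, 0]
    if len(t) >= 2 and not np.all(np.diff(t) > 0):
        problems.append("position timestamps are not strictly increasing")
    dur = session.duration_s
    if len(t) == 0:
        problems.append("position track is empty")
    else:
        if t[0] > 1.0:
            problems.append(f"position starts {t[0]:.2f} s after signal start (> 1 s)")
        if dur - t[-1] > 1.0:
            problems.append(
                f"position ends {dur - t[-1]:.2f} s before signal end (> 1 s coverage gap)"
            )
    return problems


def write_session_bundle(session: LFPSession, path: str | Path, overwrite: bool = False) -> None:
    """Write a session bundle directory (``signals.h5`` + ``meta.json`` + ``position.csv``)."""
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not overwrite:
        raise FileExistsError(f"bundle exists: {path} (pass overwrite=True)")
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "signals.h5", "w") as f:
        f.create_dataset("lfp_uv", data=np.asarray(session.signals, dtype=np.float32))
    meta = {
        "mouse_id": session.mouse_id,
        "genotype": session.genotype.value,
        "age_group": session.age_group.value,
        "session_index": session.session_index,
        "sample_rate": session.sample_rate,
        "sites": [
            {
                "site_id": s.site_id,
                "shank_index": s.shank_index,
                "depth_index": s.depth_index,
                "region": s.region.value,
                "usable": s.usable,
            }
            for s in session.sites
        ],
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    pd.DataFrame(session.position, columns=["t_s", "x_cm", "y_cm"]).to_csv(
        path / "position.csv", index=False
    )


def read_session_bundle(path: str | Path) -> LFPSession:
    """Read and validate a session bundle written by :func:`write_session_bundle`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"bundle sidecar missing: {meta_path}")
    meta = json.loads(meta_path.read_text())
    try:
        sites = [
            ElectrodeSite(
                site_id=s["site_id"],
                shank_index=int(s["shank_index"]),
                depth_index=int(s["depth_index"]),
                region=Region(s["region"]),
                usable=bool(s.get("usable", True)),
            )
            for s in meta["sites"]
        ]
        session = LFPSession(
            mouse_id=meta["mouse_id"],
            genotype=Genotype(meta["genotype"]),
            age_group=AgeGroup(meta["age_group"]),
            session_index=int(meta["session_index"]),
            sample_rate=float(meta["sample_rate"]),
            signals=_read_signals(path / "signals.h5"),
            sites=sites,
            position=pd.read_csv(path / "position.csv").to_numpy(dtype=float),
        )
    except (KeyError, ValueError) as exc:
        raise ValueError(f"invalid bundle {path}: {exc}") from exc
    problems = validate_session(session)
    if problems:
        raise ValueError(f"invalid session in {path}: " + "; ".join(problems))
    return session


def _read_signals(h5path: Path) -> np.ndarray:
    with h5py.File(h5path, "r") as f:
        return f["lfp_uv"][:].astype(np.float64)


def convert_crcns_hc26(source_dir: str | Path, dest_dir: str | Path) -> None:
    """Converter stub for the publicly deposited recordings (CRCNS hc-26).

    The deposited data ship as 0–300 Hz filtered LFP, MUA spike times,
    position tracking, and per-site metadata. Converting them to session
    bundles requires mapping each recording's channel table onto
    :class:`ElectrodeSite` rows (region labels from the deposited metadata)
    and writing the LFP matrix to ``signals.h5`` as microvolts. The download
    is several tens of GB and is deliberately not required by any test or
    analysis in this package; all analyses run on synthetic sessions with
    known ground truth.
    """
    raise NotImplementedError(
        "CRCNS hc-26 ingestion is a documented stub: download the repository, "
        "then write one bundle per session via write_session_bundle()."
    )
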
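"""Axial pore profiles for claudin seam assemblies.

A *seam* is one cis-dimer interface configuration of a claudin tetramer
(cis-dimer A or B crossed with pore I or II), treated as a replicate
system.  Each seam is characterised by a one-dimensional sampling along
the pore centerline: axial position ``z`` (Å, increasing toward the
extracellular side), pore radius ``r(z)`` (Å) and electrostatic
potential ``V(z)`` (kT/e, thermal energy per elementary charge;
1 kT/e ~= 26.7 mV at 310 K).

Profiles are stored on disk as tab-separated text, one file per seam,
with seam metadata in a ``#``-prefixed key/value header block.  Floats
are serialised with 17 significant digits so a write/read round trip is
an exact identity.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "KT_E_TO_MV_310K",
    "AxialProfile",
    "SeamSet",
    "ProfileFormatError",
    "ProfileValidationError",
    "read_profile",
    "read_profiles",
    "write_profile",
    "write_profiles",
    "resample",
]

#: Display conversion factor: one kT/e at 310 K expressed in millivolts.
KT_E_TO_MV_310K = 26.7

ISOFORM_LABELS = ("iso1", "iso2")
DIMER_LABELS = ("A", "B")
PORE_LABELS = ("I", "II")

_FLOAT_FMT = "%.17g"
_COLUMNS = ("z", "radius", "potential")


class ProfileFormatError(ValueError):
    """The profile file does not follow the expected TSV dialect."""


class ProfileValidationError(ValueError):
    """The parsed profile violates an AxialProfile invariant."""


@dataclass(frozen=True)
class AxialProfile:
    """One seam's centerline sampling.

    Parameters
    ----------
    seam_id
        Unique identifier for the seam (free text).
    isoform_label
        ``"iso1"`` (the 35 kDa species) or ``"iso2"`` (the 25 kDa species).
    dimer
        Cis-dimer label, ``"A"`` or ``"B"``.
    pore
        Pore label, ``"I"`` or ``"II"``.
    z, radius, potential
        Equal-length arrays: axial position (Å, strictly increasing),
        pore radius (Å, strictly positive) and electrostatic potential
        (kT/e, finite).
    """

    seam_id: str
    isoform_label: str
    dimer: str
    pore: str
    z: np.ndarray
    radius: np.ndarray
    potential: np.ndarray

    def __post_init__(self) -> None:
        for name in ("z", "radius", "potential"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        if self.isoform_label not in ISOFORM_LABELS:
            raise ProfileValidationError(
                f"seam {self.seam_id!r}: isoform_label must be one of "
                f"{ISOFORM_LABELS}, got {self.isoform_label!r}"
            )
        if self.dimer not in DIMER_LABELS:
            raise ProfileValidationError(
                f"seam {self.seam_id!r}: dimer must be one of {DIMER_LABELS}"
            )
        if self.pore not in PORE_LABELS:
            raise ProfileValidationError(
                f"seam {self.seam_id!r}: pore must be one of {PORE_LABELS}"
            )
        n = self.z.size
        if not (n == self.radius.size == self.potential.size):
            raise ProfileValidationError(
                f"seam {self.seam_id!r}: z/radius/potential lengths differ"
            )
        if n < 5:
            raise ProfileValidationError(
                f"seam {self.seam_id!r}: need at least 5 samples, got {n}"
            )
        if not np.all(np.isfinite(self.z)):
            raise ProfileValidationError(f"seam {self.seam_id!r}: non-finite z")
        if not np.all(np.diff(self.z) > 0):
            raise ProfileValidationError(
                f"seam {self.seam_id!r}: z must be strictly increasing"
            )
        if not np.all(np.isfinite(self.radius)) or not np.all(self.radius > 0):
            raise ProfileValidationError(
                f"seam {self.seam_id!r}: radius must be finite and strictly positive"
            )
        if not np.all(np.isfinite(self.potential)):
            raise ProfileValidationError(
                f"seam {self.seam_id!r}: potential must be finite"
            )

    @property
    def n_samples(self) -> int:
        return int(self.z.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AxialProfile):
            return NotImplemented
        return (
            self.seam_id == other.seam_id
            and self.isoform_label == other.isoform_label
            and self.dimer == other.dimer
            and self.pore == other.pore
            and np.array_equal(self.z, other.z)
            and np.array_equal(self.radius, other.radius)
            and np.array_equal(self.potential, other.potential)
        )


@dataclass(frozen=True)
class SeamSet:
    """A collection of seam profiles across one or both isoforms.

    The A/B x Pore I/II design gives at most four seams per isoform,
    so each (isoform, dimer, pore) combination may appear only once.
    """

    profiles: tuple[AxialProfile, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "profiles", tuple(self.profiles))
        ids = [p.seam_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ProfileValidationError("duplicate seam_id in SeamSet")
        combos = [(p.isoform_label, p.dimer, p.pore) for p in self.profiles]
        if len(set(combos)) != len(combos):
            raise ProfileValidationError(
                "duplicate (isoform, dimer, pore) combination in SeamSet"
            )

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def by_isoform(self, isoform_label: str) -> tuple[AxialProfile, ...]:
        return tuple(p for p in self.profiles if p.isoform_label == isoform_label)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SeamSet):
            return NotImplemented
        return self.profiles == other.profiles


# ---------------------------------------------------------------------------
# File I/O: one TSV per seam, '#'-prefixed metadata header
# ---------------------------------------------------------------------------

def write_profile(profile: AxialProfile, path: str | os.PathLike) -> None:
    """Serialise one seam profile to a TSV file with a metadata header."""
    path = Path(path)
    lines = [
        f"# seam_id\t{profile.seam_id}",
        f"# isoform\t{profile.isoform_label}",
        f"# dimer\t{profile.dimer}",
        f"# pore\t{profile.pore}",
        "\t".join(_COLUMNS),
    ]
    for zi, ri, vi in zip(profile.z, profile.radius, profile.potential):
        lines.append(
            "\t".join(_FLOAT_FMT % v for v in (zi, ri, vi))
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_profiles(seams: SeamSet, directory: str | os.PathLike) -> list[Path]:
    """Write each seam of a SeamSet to ``directory`` as ``<seam_id>.tsv``.

    Returns the list of files written.  An empty SeamSet writes nothing
    but still creates the directory.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for profile in seams:
        safe = "".join(c if (c.isalnum() or c in "-_.") else "_" for c in profile.seam_id)
        p = directory / f"{safe}.tsv"
        write_profile(profile, p)
        paths.append(p)
    return paths


def read_profile(path: str | os.PathLike) -> AxialProfile:
    """Parse one seam profile file.

    Rows are normalised to increasing ``z``; duplicate z values after
    sorting raise a validation error naming the seam.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "\t" in body:
                key, _, value = body.partition("\t")
            else:
                key, _, value = body.partition(" ")
            meta[key.strip()] = value.strip()
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            missing = [c for c in _COLUMNS if c not in header]
            if missing:
                raise ProfileFormatError(
                    f"{path}: missing column(s) {missing}; found {header}"
                )
            continue
        try:
            rows.append([float(x) for x in fields])
        except ValueError as exc:
            raise ProfileFormatError(f"{path}:{lineno}: non-numeric row") from exc
    if header is None:
        raise ProfileFormatError(f"{path}: no header line found")
    seam_id = meta.get("seam_id", path.stem)
    data = np.asarray(rows, dtype=float)
    if data.ndim != 2 or data.shape[1] < len(_COLUMNS):
        raise ProfileFormatError(f"{path}: malformed data rows")
    cols = {name: data[:, header.index(name)] for name in _COLUMNS}
    order = np.argsort(cols["z"], kind="stable")
    z = cols["z"][order]
    if np.any(np.diff(z) == 0):
        raise ProfileValidationError(
            f"seam {seam_id!r}: duplicate z values after sort normalisation"
        )
    return AxialProfile(
        seam_id=seam_id,
        isoform_label=meta.get("isoform", "iso1"),
        dimer=meta.get("dimer", "A"),
        pore=meta.get("pore", "I"),
        z=z,
        radius=cols["radius"][order],
        potential=cols["potential"][order],
    )


def read_profiles(paths: Iterable[str | os.PathLike] | str | os.PathLike) -> SeamSet:
    """Read a SeamSet from profile files or from a directory of ``*.tsv``."""
    if isinstance(paths, (str, os.PathLike)):
        p = Path(paths)
        if p.is_dir():
            paths = sorted(p.glob("*.tsv"))
        else:
            paths = [p]
    return SeamSet(tuple(read_profile(p) for p in paths))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(profile: AxialProfile, dz: float) -> AxialProfile:
    """Resample a profile onto a uniform grid of step ``dz``.

    The new grid spans ``[min(z), max(z)]``; the right endpoint is always
    included so the axial extent is preserved.  Radius and potential are
    linearly interpolated; seam metadata is carried over unchanged.
    """
    if not dz > 0:
        raise ValueError(f"dz must be > 0, got {dz}")
    z0, z1 = float(profile.z[0]), float(profile.z[-1])
    n = int(np.floor((z1 - z0) / dz + 1e-12))
    grid = z0 + dz * np.arange(n + 1)
    if grid[-1] < z1 - 1e-12 * max(1.0, abs(z1)):
        grid = np.append(grid, z1)
    else:
        grid[-1] = z1
    return replace(
        profile,
        z=grid,
        radius=np.interp(grid, profile.z, profile.radius),
        potential=np.interp(grid, profile.z, profile.potential),
    )
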
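"""Coordinate and scattering-curve containers with plain-text readers/writers.

Structures are coarse bead models (one pseudo-atom per record) stored in
fixed-column PDB; scattering curves are GNOM/PRIMUS-style 3-column ``.dat``
text (momentum transfer s in 1/Angstrom, intensity, error).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("translinflex")

__all__ = [
    "Bead",
    "Structure",
    "ScatteringCurve",
    "read_structure",
    "write_structure",
    "read_curve",
    "write_curve",
    "StructureParseError",
    "CurveParseError",
]


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed; names the bad line."""


class CurveParseError(ValueError):
    """Raised when a scattering-curve file cannot be parsed."""


@dataclass(frozen=True)
class Bead:
    """One pseudo-atom: chain, residue number/name, bead name, position, weight."""

    chain: str
    resnum: int
    resname: str
    name: str
    x: float
    y: float
    z: float
    weight: float = 1.0


@dataclass
class Structure:
    """A labelled bead set with per-bead scattering weight.

    Coordinates are in Angstrom. Residue numbering is 1-based PDB style;
    bead order within a chain is preserved by all readers and writers.
    """

    beads: list[Bead]
    metadata: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for b in self.beads:
            if not np.isfinite([b.x, b.y, b.z]).all():
                raise ValueError(f"non-finite coordinates on bead {b}")
            if not (b.weight > 0):
                raise ValueError(f"scattering weight must be > 0, got {b.weight}")
            key = (b.chain, b.resnum, b.name)
            if key in seen:
                raise ValueError(f"duplicate bead {key} within chain")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.beads)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) float array of bead positions in Angstrom."""
        return np.array([[b.x, b.y, b.z] for b in self.beads], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return np.array([b.weight for b in self.beads], dtype=float)

    @property
    def chains(self) -> list[str]:
        """Chain ids in order of first appearance."""
        out: list[str] = []
        for b in self.beads:
            if b.chain not in out:
                out.append(b.chain)
        return out

    def chain_beads(self, chain: str) -> list[Bead]:
        return [b for b in self.beads if b.chain == chain]

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with bead positions replaced (labels kept)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.beads), 3):
            raise ValueError(f"expected shape {(len(self.beads), 3)}, got {coords.shape}")
        beads = [
            replace(b, x=float(c[0]), y=float(c[1]), z=float(c[2]))
            for b, c in zip(self.beads, coords)
        ]
        return Structure(beads, metadata=self.metadata)

    def rg(self) -> float:
        """Weighted radius of gyration of the bead set, in Angstrom."""
        xyz = self.coords
        w = self.weights
        com = np.average(xyz, axis=0, weights=w)
        return float(np.sqrt(np.average(np.sum((xyz - com) ** 2, axis=1), weights=w)))


@dataclass
class ScatteringCurve:
    """I(s) on a strictly increasing momentum-transfer grid, with errors."""

    s: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.s.shape == self.intensity.shape == self.sigma.shape):
            raise ValueError("s, intensity and sigma must have identical shapes")
        if self.s.ndim != 1 or self.s.size < 1:
            raise ValueError("curve needs at least one point")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("s grid must be strictly increasing")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be >= 0")
        if not np.isfinite(self.intensity).all():
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return self.s.size

    def window(self, s_min: float, s_max: float) -> "ScatteringCurve":
        """Sub-curve restricted to s_min <= s <= s_max."""
        m = (self.s >= s_min) & (self.s <= s_max)
        if not m.any():
            raise ValueError(f"no points in window ({s_min}, {s_max})")
        return ScatteringCurve(self.s[m], self.intensity[m], self.sigma[m], self.label)


# --- PDB-subset fixed-column IO -------------------------------------------------
# Only ATOM/HETATM, TER and END records are understood; occupancy/B-factor are
# ignored on read and written as 1.00/0.00. Scattering weights default to 1.0.

def read_structure(text: str) -> Structure:
    if not text.strip():
        raise StructureParseError("empty structure input")
    beads: list[Bead] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        try:
            name = line[12:16].strip() or "CA"
            resname = line[17:20].strip() or "GLY"
            chain = line[21].strip() or "A"
            resnum = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (ValueError, IndexError) as exc:
            raise StructureParseError(f"malformed ATOM record on line {lineno}: {exc}") from exc
        beads.append(Bead(chain, resnum, resname, name, x, y, z, 1.0))
    if not beads:
        raise StructureParseError("no ATOM/HETATM records found")
    return Structure(beads)


def write_structure(structure: Structure) -> str:
    lines = []
    prev_chain = None
    serial = 0
    for b in structure.beads:
        if prev_chain is not None and b.chain != prev_chain:
            lines.append("TER")
        prev_chain = b.chain
        serial += 1
        lines.append(
            f"ATOM  {serial % 100000:5d} {b.name:>4.4s} {b.resname:<3.3s} "
            f"{b.chain[:1]}{b.resnum:4d}    "
            f"{b.x:8.3f}{b.y:8.3f}{b.z:8.3f}  1.00  0.00"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_curve(text: str, label: str = "") -> ScatteringCurve:
    """Parse whitespace-delimited (s, I[, sigma]) text; '#' and non-numeric
    leading tokens mark comment lines, which are skipped."""
    s_vals: list[float] = []
    i_vals: list[float] = []
    e_vals: list[float] = []
    missing_sigma = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        try:
            s = float(fields[0])
            inten = float(fields[1])
        except (ValueError, IndexError):
            continue  # header / comment line
        if len(fields) >= 3:
            try:
                sig = float(fields[2])
            except ValueError:
                raise CurveParseError(f"bad sigma field on line {lineno}")
            if sig < 0:
                raise CurveParseError(f"negative sigma on line {lineno}")
        else:
            sig = 0.0
            missing_sigma += 1
        s_vals.append(s)
        i_vals.append(inten)
        e_vals.append(sig)
    if len(s_vals) < 2:
        raise CurveParseError("need at least 2 data rows")
    if missing_sigma:
        logger.warning("%d rows had no sigma column; set sigma=0", missing_sigma)
    order = np.argsort(s_vals, kind="stable")
    s_arr = np.array(s_vals)[order]
    if np.any(np.diff(s_arr) <= 0):
        raise CurveParseError("duplicate or non-increasing s values")
    return ScatteringCurve(s_arr, np.array(i_vals)[order], np.array(e_vals)[order], label)


def write_curve(curve: ScatteringCurve) -> str:
    lines = [f"# {curve.label}" if curve.label else "# scattering curve (s, I, sigma)"]
    for s, inten, sig in zip(curve.s, curve.intensity, curve.sigma):
        lines.append(f"{s:.6e} {inten:.6e} {sig:.6e}")
    return "\n".join(lines) + "\n"
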
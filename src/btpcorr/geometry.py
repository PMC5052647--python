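"""Backbone torsion geometry: dihedral computation, torsion indexing,
torsion positions and inter-torsion distances, secondary-structure typing.

A protein of N residues contributes 2N-2 analyzable backbone torsions:
phi of the N-terminal residue and psi of the C-terminal residue are
undefined and excluded. Torsions are indexed 1..2N-2 in sequence order

    psi(1), phi(2), psi(2), ..., phi(N)

so that correlation-matrix axes run N-terminus to C-terminus. The
position of a torsion is the midpoint of its central bond (N-CA for phi,
CA-C for psi); inter-torsion distance is the Euclidean distance between
midpoints in a designated reference frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "DegenerateDihedralError",
    "TorsionSeries",
    "TorsionIndexMap",
    "StructureFrame",
    "SecondaryStructureAssignment",
    "dihedral_angle",
    "build_torsion_index",
    "extract_torsion_series",
    "torsion_position",
    "inter_torsion_distance",
    "map_secondary_structure",
    "pair_type",
    "read_pdb_frames",
    "read_dssp_codes",
    "write_torsion_table",
    "read_torsion_table",
]

BACKBONE_ATOMS = ("N", "CA", "C")

#: DSSP single-letter codes accepted on input; blank/'-'/'C' mean coil.
DSSP_CODES = frozenset("HBEGITS") | {"", "-", "C"}


class DegenerateDihedralError(ValueError):
    """Raised when a dihedral is undefined (collinear bond vectors)."""


@dataclass
class TorsionSeries:
    """Angle time series of one indexed backbone torsion, in degrees.

    Angles follow the (-180, 180] convention throughout the package.
    """

    index: int
    residue_number: int
    kind: Literal["phi", "psi"]
    angles: np.ndarray
    ss_class: str | None = None  # "alpha" | "beta" | "L"

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)

    def __len__(self) -> int:
        return self.angles.size


@dataclass(frozen=True)
class TorsionIndexMap:
    """Ordered 1..2N-2 index of the analyzable backbone torsions."""

    n_residues: int
    entries: tuple[tuple[int, int, str], ...]  # (index, residue_number, kind)

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, index: int) -> tuple[int, int, str]:
        """Return (index, residue_number, kind) for 1-based torsion index."""
        if not 1 <= index <= len(self.entries):
            raise KeyError(f"torsion index {index} outside 1..{len(self.entries)}")
        return self.entries[index - 1]


@dataclass
class StructureFrame:
    """Backbone (N, CA, C) coordinates of one snapshot, in Angstroms."""

    residue_numbers: tuple[int, ...]
    coords: dict[tuple[int, str], np.ndarray]  # (residue_number, atom) -> xyz

    def atom(self, residue_number: int, name: str) -> np.ndarray:
        try:
            return self.coords[(residue_number, name)]
        except KeyError:
            raise KeyError(
                f"missing backbone atom {name} of residue {residue_number}"
            ) from None


@dataclass
class SecondaryStructureAssignment:
    """Per-residue class in {alpha, beta, L} from majority-voted DSSP codes."""

    classes: dict[int, str]
    votes: dict[int, list[str]] = field(default_factory=dict)

    def __getitem__(self, residue_number: int) -> str:
        return self.classes[residue_number]


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Dihedral angle defined by four points, degrees in (-180, 180].

    Sign follows the IUPAC convention: looking from p2 toward p3, a
    clockwise rotation of the far (p3-p4) plane relative to the near
    (p1-p2) plane is positive.

    Raises
    ------
    DegenerateDihedralError
        If a bond vector vanishes or consecutive bonds are parallel,
        in which case the torsion is geometrically undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if not np.all(np.isfinite(b)) or np.linalg.norm(b) == 0.0:
            raise DegenerateDihedralError("zero-length or non-finite bond vector")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateDihedralError("collinear consecutive bond vectors")
    # atan2 of (b1 x b2) x (b2 x b3) projected on b2 versus n1.n2
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def build_torsion_index(n_residues: int) -> TorsionIndexMap:
    """Build the 1..2N-2 torsion index for a chain of N residues.

    Ordering is psi(1), phi(2), psi(2), ..., phi(N): phi of residue 1
    and psi of residue N do not exist.
    """
    if n_residues < 2:
        raise ValueError("a chain needs at least 2 residues to define a torsion")
    entries: list[tuple[int, int, str]] = []
    idx = 1
    for res in range(1, n_residues + 1):
        if res > 1:
            entries.append((idx, res, "phi"))
            idx += 1
        if res < n_residues:
            entries.append((idx, res, "psi"))
            idx += 1
    assert len(entries) == 2 * n_residues - 2
    return TorsionIndexMap(n_residues=n_residues, entries=tuple(entries))


def _torsion_atoms(entry: tuple[int, int, str]) -> list[tuple[int, str]]:
    _, res, kind = entry
    if kind == "phi":
        return [(res - 1, "C"), (res, "N"), (res, "CA"), (res, "C")]
    return [(res, "N"), (res, "CA"), (res, "C"), (res + 1, "N")]


def extract_torsion_series(
    frames: Sequence[StructureFrame], index_map: TorsionIndexMap
) -> list[TorsionSeries]:
    """Compute every indexed torsion across a list of frames.

    phi(i) uses C(i-1)-N(i)-CA(i)-C(i); psi(i) uses N(i)-CA(i)-C(i)-N(i+1).
    """
    out: list[TorsionSeries] = []
    for entry in index_map.entries:
        idx, res, kind = entry
        atoms = _torsion_atoms(entry)
        angles = np.empty(len(frames))
        for f_i, frame in enumerate(frames):
            try:
                pts = [frame.atom(r, a) for r, a in atoms]
            except KeyError as exc:
                raise KeyError(f"frame {f_i}: {exc.args[0]}") from None
            angles[f_i] = dihedral_angle(*pts)
        out.append(TorsionSeries(index=idx, residue_number=res, kind=kind, angles=angles))
    return out


def torsion_position(frame: StructureFrame, entry: tuple[int, int, str]) -> np.ndarray:
    """Midpoint of the torsion's central bond (phi: N-CA, psi: CA-C)."""
    _, res, kind = entry
    if kind == "phi":
        a, b = frame.atom(res, "N"), frame.atom(res, "CA")
    else:
        a, b = frame.atom(res, "CA"), frame.atom(res, "C")
    return (np.asarray(a, float) + np.asarray(b, float)) / 2.0


def inter_torsion_distance(
    reference: StructureFrame, index_map: TorsionIndexMap, i: int, j: int
) -> float:
    """Euclidean distance (A) between central-bond midpoints of torsions i, j.

    The 8 A cutoff applied downstream classifies a pair as spatially
    local when distance <= 8 and long-range otherwise.
    """
    if i == j:
        warnings.warn("self-pair distance requested; returning 0", stacklevel=2)
        return 0.0
    pi = torsion_position(reference, index_map.entry(i))
    pj = torsion_position(reference, index_map.entry(j))
    return float(np.linalg.norm(pi - pj))


def map_secondary_structure(
    dssp_codes: Sequence[dict[int, str]],
    residue_numbers: Iterable[int] | None = None,
) -> SecondaryStructureAssignment:
    """Map per-structure DSSP codes to {alpha, beta, L} by majority vote.

    H -> alpha, E -> beta, everything else (B, G, I, T, S, blank) -> L.
    With several input structures each residue takes the class observed
    most often; ties break toward L, the conservative loop call.
    Residues missing from a structure's DSSP output count as L with a
    warning.
    """
    if not dssp_codes:
        raise ValueError("at least one DSSP code table required")
    if residue_numbers is None:
        residue_numbers = sorted({r for table in dssp_codes for r in table})
    residue_numbers = list(residue_numbers)

    votes: dict[int, list[str]] = {r: [] for r in residue_numbers}
    for s_i, table in enumerate(dssp_codes):
        for res in residue_numbers:
            code = table.get(res)
            if code is None:
                warnings.warn(
                    f"residue {res} absent from DSSP table {s_i}; counted as L",
                    stacklevel=2,
                )
                votes[res].append("L")
                continue
            code = code.strip().upper()
            if code not in DSSP_CODES:
                raise ValueError(f"unknown DSSP code {code!r} for residue {res}")
            votes[res].append("alpha" if code == "H" else "beta" if code == "E" else "L")

    classes: dict[int, str] = {}
    for res, vs in votes.items():
        counts = {c: vs.count(c) for c in ("alpha", "beta", "L")}
        best = max(counts.values())
        winners = [c for c, n in counts.items() if n == best]
        classes[res] = winners[0] if len(winners) == 1 else "L"
    return SecondaryStructureAssignment(classes=classes, votes=votes)


def pair_type(ss_i: str, ss_j: str) -> str:
    """Pool alpha and beta: returns 'ab-ab', 'ab-L' or 'L-L' (symmetric)."""
    valid = {"alpha", "beta", "L"}
    if ss_i not in valid or ss_j not in valid:
        raise ValueError(f"invalid secondary-structure class in ({ss_i}, {ss_j})")
    n_loop = (ss_i == "L") + (ss_j == "L")
    return ("ab-ab", "ab-L", "L-L")[n_loop]


# ---------------------------------------------------------------------------
# File interfaces


def read_pdb_frames(path, models: Sequence[int] | None = None) -> list[StructureFrame]:
    """Read backbone N/CA/C coordinates from a PDB file via Biopython.

    Each MODEL becomes one StructureFrame; by default only the first
    model is read (pass explicit 0-based model indices to override).
    First chain only; altloc first-occurrence.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    all_models = list(structure)
    picks = [all_models[0]] if models is None else [all_models[m] for m in models]
    frames = []
    for model in picks:
        chain = next(iter(model))
        coords: dict[tuple[int, str], np.ndarray] = {}
        residues = []
        for residue in chain:
            if residue.id[0] != " ":
                continue
            resnum = residue.id[1]
            residues.append(resnum)
            for name in BACKBONE_ATOMS:
                if name in residue:
                    coords[(resnum, name)] = np.array(residue[name].coord, dtype=float)
        frames.append(StructureFrame(residue_numbers=tuple(residues), coords=coords))
    return frames


def read_dssp_codes(path) -> dict[int, str]:
    """Read a two-column (residue_number, DSSP code) whitespace table."""
    table: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            table[int(parts[0])] = parts[1] if len(parts) > 1 else ""
    return table


def write_torsion_table(path, series: Sequence[TorsionSeries]) -> None:
    """Write the torsion-series TSV: header 'snapshot t1..t{2N-2}', degrees.

    Values are written with 6 decimal places; read_torsion_table
    round-trips them bit-identically at that precision.
    """
    series = sorted(series, key=lambda s: s.index)
    m = len(series[0])
    if any(len(s) != m for s in series):
        raise ValueError("all torsion series must share the snapshot count")
    with open(path, "w") as fh:
        fh.write("snapshot\t" + "\t".join(f"t{s.index}" for s in series) + "\n")
        mat = np.column_stack([s.angles for s in series])
        for i in range(m):
            fh.write(str(i) + "\t" + "\t".join(f"{v:.6f}" for v in mat[i]) + "\n")


def read_torsion_table(path) -> list[TorsionSeries]:
    """Read the torsion-series TSV written by :func:`write_torsion_table`.

    Residue/kind metadata is reconstructed from the sequence-order
    indexing convention (psi1, phi2, psi2, ...).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c.startswith("t")]
    indices = sorted(int(c[1:]) for c in cols)
    n_res = len(indices) // 2 + 1
    imap = build_torsion_index(n_res)
    out = []
    for idx in indices:
        _, res, kind = imap.entry(idx)
        out.append(
            TorsionSeries(
                index=idx,
                residue_number=res,
                kind=kind,
                angles=df[f"t{idx}"].to_numpy(dtype=float),
            )
        )
    return out
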
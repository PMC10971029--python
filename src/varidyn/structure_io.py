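"""Structures, trajectory ensembles, atom selections and frame conventions.

Coordinates are Cartesian and in Angstrom throughout. A :class:`Structure`
is a single conformation; a :class:`TrajectoryEnsemble` is an ordered stack
of conformations of the same atoms (one replicate of one variant at one
temperature). Multi-model PDB is the canonical on-disk ensemble format; a
minimal XYZ dialect is supported as a fallback for coordinate-only data.

Residue numbers are author numbering from the source file and are never
renumbered; residue ranges in selection expressions are inclusive on both
ends. Atom indices are 0-based internally.
"""

from __future__ import annotations

import json
import math
import re
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "Structure",
    "TrajectoryEnsemble",
    "Selection",
    "read_ensemble",
    "write_ensemble",
    "read_structure",
    "write_structure",
    "resolve_selection",
    "drop_equilibration",
    "convert_rdata",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom's identity: index, name, and residue context.

    ``atom_index`` is 0-based and equals the atom's position in its
    structure's atom list. ``residue_number`` is the author numbering of the
    source file.
    """

    atom_index: int
    atom_name: str
    residue_number: int
    residue_name: str
    chain_id: str


def _check_atom_uniqueness(atoms: list[AtomRecord]) -> None:
    seen: set[tuple[str, int, str]] = set()
    for a in atoms:
        key = (a.chain_id, a.residue_number, a.atom_name)
        if key in seen:
            raise ValueError(f"duplicate atom {key}; (chain, residue, atom name) must be unique")
        seen.add(key)


@dataclass
class Structure:
    """A single conformation: atom metadata plus an N x 3 coordinate matrix [A]."""

    atoms: list[AtomRecord]
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an N x 3 matrix")
        if self.coordinates.shape[0] != len(self.atoms):
            raise ValueError(
                f"coordinate rows ({self.coordinates.shape[0]}) != atom count ({len(self.atoms)})"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        for i, a in enumerate(self.atoms):
            if a.atom_index != i:
                raise ValueError(f"atom_index {a.atom_index} at list position {i}")
        _check_atom_uniqueness(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def chain_ids(self) -> set[str]:
        return {a.chain_id for a in self.atoms}


@dataclass
class TrajectoryEnsemble:
    """Ordered frames of one replicate: shared atoms plus a T x N x 3 array [A].

    ``frame_interval`` is the recording interval in ps. ``label`` names the
    variant, ``replicate`` the replicate index and ``temperature`` the
    simulation temperature in K.
    """

    atoms: list[AtomRecord]
    frames: np.ndarray
    frame_interval: float = 2.0
    label: str = ""
    replicate: int = 0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be a T x N x 3 array")
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble must contain at least one frame")
        if self.frames.shape[1] != len(self.atoms):
            raise ValueError(
                f"frame atom count ({self.frames.shape[1]}) != atom list length ({len(self.atoms)})"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite coordinates")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        _check_atom_uniqueness(self.atoms)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def structure(self, frame: int = 0) -> Structure:
        """The single-frame :class:`Structure` at frame index ``frame``."""
        return Structure(atoms=self.atoms, coordinates=self.frames[frame].copy())

    def chain_ids(self) -> set[str]:
        return {a.chain_id for a in self.atoms}


@dataclass
class Selection:
    """A resolved atom selection: the expression and the matching indices.

    ``resolved_indices`` is strictly increasing and valid for the structure
    the expression was resolved against.
    """

    expression: str
    resolved_indices: np.ndarray

    def __post_init__(self) -> None:
        self.resolved_indices = np.asarray(self.resolved_indices, dtype=int)
        if self.resolved_indices.size and np.any(np.diff(self.resolved_indices) <= 0):
            raise ValueError("resolved_indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.resolved_indices.size)


# --------------------------------------------------------------------------
# selection language
# --------------------------------------------------------------------------

_RESID_RANGE = re.compile(r"^(-?\d+)-(-?\d+)$")


def resolve_selection(obj: Structure | TrajectoryEnsemble, expression: str) -> Selection:
    """Resolve a selection expression against a structure or ensemble.

    The expression is a conjunction of clauses joined by ``and``:

    * ``all`` — every atom;
    * ``chain <id>`` — atoms of the named chain;
    * ``resid <n>`` or ``resid <a>-<b>`` — residue number(s), inclusive;
    * ``name <atom name>`` — e.g. ``name CA``.

    An empty match is allowed but raises a ``UserWarning``. Referencing a
    chain id absent from the structure is a hard error.
    """
    atoms = obj.atoms
    present_chains = {a.chain_id for a in atoms}
    mask = np.ones(len(atoms), dtype=bool)

    clauses = [c.strip() for c in expression.split(" and ")]
    if not clauses or any(not c for c in clauses):
        raise ValueError(f"empty clause in selection expression {expression!r}")
    for clause in clauses:
        parts = clause.split()
        kind = parts[0].lower()
        if kind == "all" and len(parts) == 1:
            continue
        if len(parts) != 2:
            raise ValueError(f"cannot parse selection clause {clause!r}")
        value = parts[1]
        if kind == "chain":
            if value not in present_chains:
                raise ValueError(
                    f"chain {value!r} not present in structure (has {sorted(present_chains)})"
                )
            mask &= np.array([a.chain_id == value for a in atoms])
        elif kind == "resid":
            m = _RESID_RANGE.match(value)
            if m:
                lo, hi = int(m.group(1)), int(m.group(2))
            elif re.fullmatch(r"-?\d+", value):
                lo = hi = int(value)
            else:
                raise ValueError(f"cannot parse residue clause {clause!r}")
            if hi < lo:
                raise ValueError(f"inverted residue range in {clause!r}")
            mask &= np.array([lo <= a.residue_number <= hi for a in atoms])
        elif kind == "name":
            mask &= np.array([a.atom_name == value for a in atoms])
        else:
            raise ValueError(f"unknown selection keyword {parts[0]!r} in {clause!r}")

    indices = np.nonzero(mask)[0]
    if indices.size == 0:
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    return Selection(expression=expression, resolved_indices=indices)


# --------------------------------------------------------------------------
# equilibration convention
# --------------------------------------------------------------------------

def drop_equilibration(ensemble: TrajectoryEnsemble, fraction: float = 1.0 / 3.0) -> TrajectoryEnsemble:
    """Discard the initial ``fraction`` of frames as equilibration.

    Keeps the last ``ceil(T * (1 - fraction))`` frames, mirroring the
    convention of analysing only the production tail of each replicate
    (e.g. the final 10 ns of a 15 ns run, fraction 1/3). The input ensemble
    is left untouched.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    T = ensemble.n_frames
    # keep ceil(T*(1-fraction)) frames; computed as T - floor(T*fraction)
    # with an epsilon guard so 15 * (1/3) drops exactly 5 frames
    keep = T - math.floor(T * fraction + 1e-9)
    if keep < 1:
        raise ValueError("dropping equilibration would leave no frames")
    return replace(ensemble, frames=ensemble.frames[T - keep :].copy())


# --------------------------------------------------------------------------
# PDB / XYZ I/O
# --------------------------------------------------------------------------

def _scan_pdb_models(lines: list[str]) -> list[int]:
    """Per-model ATOM/HETATM counts; a file without MODEL records is one model."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model_record = False
    for line in lines:
        rec = line[:6]
        if rec.startswith("MODEL"):
            saw_model_record = True
            in_model = True
            current = 0
        elif rec.startswith("ENDMDL"):
            counts.append(current)
            in_model = False
        elif rec.startswith(("ATOM  ", "HETATM")):
            current += 1
    if not saw_model_record:
        counts = [current] if current else []
    elif in_model:  # unterminated final model
        counts.append(current)
    return counts


def _check_insertion_codes(lines: list[str]) -> None:
    for line in lines:
        if line.startswith(("ATOM  ", "HETATM")) and len(line) > 26 and line[26] not in (" ", ""):
            raise ValueError(
                f"insertion code {line[26]!r} at residue {line[22:26].strip()} is not supported"
            )


def _atoms_from_atom_array(arr: struc.AtomArray) -> list[AtomRecord]:
    return [
        AtomRecord(
            atom_index=i,
            atom_name=str(arr.atom_name[i]),
            residue_number=int(arr.res_id[i]),
            residue_name=str(arr.res_name[i]),
            chain_id=str(arr.chain_id[i]),
        )
        for i in range(arr.array_length())
    ]


def read_ensemble(
    path: str | Path,
    format: str = "pdb",
    frame_interval: float = 2.0,
    label: str = "",
    replicate: int = 0,
    temperature: float = 300.0,
) -> TrajectoryEnsemble:
    """Read a multi-frame ensemble from a multi-model PDB or XYZ file.

    All models must share an identical atom ordering; atom metadata is taken
    from the first model. A file with zero models is a hard error, as is a
    model whose atom count differs from the first (the error names the
    offending 1-based model index).
    """
    path = Path(path)
    if format == "pdb":
        pdbf = PDBFile.read(str(path))
        counts = _scan_pdb_models(pdbf.lines)
        if not counts:
            raise ValueError(f"{path}: no models / ATOM records found")
        bad = [i for i, c in enumerate(counts) if c != counts[0]]
        if bad:
            raise ValueError(
                f"{path}: model {bad[0] + 1} has {counts[bad[0]]} atoms, "
                f"model 1 has {counts[0]}"
            )
        _check_insertion_codes(pdbf.lines)
        stack = pdbf.get_structure(model=None, altloc="first")
        first = stack[0] if isinstance(stack, struc.AtomArrayStack) else stack
        atoms = _atoms_from_atom_array(first)
        frames = np.asarray(stack.coord, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
    elif format == "xyz":
        atoms, frames = _read_xyz(path)
    else:
        raise ValueError(f"unknown ensemble format {format!r}")
    return TrajectoryEnsemble(
        atoms=atoms,
        frames=frames,
        frame_interval=frame_interval,
        label=label,
        replicate=replicate,
        temperature=temperature,
    )


def write_ensemble(ensemble: TrajectoryEnsemble, path: str | Path, format: str = "pdb") -> None:
    """Write an ensemble as a multi-model PDB (or XYZ) file."""
    path = Path(path)
    if format == "pdb":
        T, n = ensemble.n_frames, ensemble.n_atoms
        stack = struc.AtomArrayStack(T, n)
        stack.coord = ensemble.frames.astype(np.float32)
        stack.chain_id = np.array([a.chain_id for a in ensemble.atoms])
        stack.res_id = np.array([a.residue_number for a in ensemble.atoms])
        stack.res_name = np.array([a.residue_name for a in ensemble.atoms])
        stack.atom_name = np.array([a.atom_name for a in ensemble.atoms])
        stack.element = np.array([a.atom_name[:1] for a in ensemble.atoms])
        stack.hetero = np.zeros(n, dtype=bool)
        pdbf = PDBFile()
        pdbf.set_structure(stack)
        pdbf.write(str(path))
    elif format == "xyz":
        _write_xyz(ensemble, path)
    else:
        raise ValueError(f"unknown ensemble format {format!r}")


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a single conformation (the first model of the file)."""
    return read_ensemble(path, format=format).structure(0)


def write_structure(structure: Structure, path: str | Path, format: str = "pdb") -> None:
    ens = TrajectoryEnsemble(atoms=structure.atoms, frames=structure.coordinates[None])
    write_ensemble(ens, path, format=format)


def _read_xyz(path: Path) -> tuple[list[AtomRecord], np.ndarray]:
    # Minimal XYZ dialect: per frame, an atom count line, a comment line and
    # one "<name> x y z" line per atom. Carries no chain/residue metadata:
    # atoms become residues 1..N of chain "A".
    lines = path.read_text().splitlines()
    pos = 0
    frames: list[np.ndarray] = []
    names: list[str] | None = None
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos].strip())
        block = lines[pos + 2 : pos + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: truncated XYZ frame at line {pos + 1}")
        frame_names = [ln.split()[0] for ln in block]
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        if names is None:
            names = frame_names
        elif frame_names != names or len(block) != len(names):
            raise ValueError(f"{path}: model {len(frames) + 1} atom list differs from model 1")
        frames.append(coords)
        pos += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    atoms = [
        AtomRecord(atom_index=i, atom_name=nm, residue_number=i + 1, residue_name="GLY", chain_id="A")
        for i, nm in enumerate(names)  # type: ignore[arg-type]
    ]
    return atoms, np.stack(frames)


def _write_xyz(ensemble: TrajectoryEnsemble, path: Path) -> None:
    with open(path, "w") as fh:
        for t in range(ensemble.n_frames):
            fh.write(f"{ensemble.n_atoms}\n")
            fh.write(f"frame {t} label={ensemble.label} t_ps={t * ensemble.frame_interval}\n")
            for a, (x, y, z) in zip(ensemble.atoms, ensemble.frames[t]):
                fh.write(f"{a.atom_name} {x:.6f} {y:.6f} {z:.6f}\n")


# --------------------------------------------------------------------------
# R-serialized coordinate cache converter
# --------------------------------------------------------------------------

_R_DUMP_SCRIPT = r"""
args <- commandArgs(trailingOnly = TRUE)
rdata <- args[1]; outdir <- args[2]
env <- new.env()
loaded <- load(rdata, envir = env)
flatten <- function(name, obj, sink) {
  if (is.matrix(obj) && is.numeric(obj) && ncol(obj) %% 3 == 0) {
    sink[[name]] <- obj
  } else if (is.list(obj)) {
    for (nm in seq_along(obj)) {
      sub <- if (!is.null(names(obj)) && nzchar(names(obj)[nm])) names(obj)[nm] else nm
      sink <- flatten(paste(name, sub, sep = "."), obj[[nm]], sink)
    }
  }
  sink
}
mats <- list()
for (nm in loaded) mats <- flatten(nm, get(nm, envir = env), mats)
if (length(mats) == 0) {
  stop("no numeric matrix with a multiple-of-3 column count found in ", rdata)
}
for (nm in names(mats)) {
  safe <- gsub("[^A-Za-z0-9._-]", "_", nm)
  write.table(mats[[nm]], file.path(outdir, paste0(safe, ".csv")),
              sep = ",", row.names = FALSE, col.names = FALSE)
}
writeLines(names(mats), file.path(outdir, "OBJECTS.txt"))
"""


def convert_rdata(rdata_path: str | Path, out_dir: str | Path) -> list[Path]:
    """Convert an R-serialized coordinate cache into multi-model PDB files.

    Expected object layout: the ``.RData`` file contains one or more numeric
    matrices of shape ``T x 3N`` — one row per cached frame, columns
    ``(x1, y1, z1, x2, ...)`` as produced by the bio3d ``xyz`` convention —
    either as top-level objects or nested in (named) lists. Each matrix is
    emitted as one multi-model PDB of N pseudo-C-alpha atoms (chain ``A``,
    residues ``1..N``; the cache stores no residue metadata).

    Requires ``Rscript`` on PATH. Fails loudly, with R's own message, on any
    layout mismatch.
    """
    rdata_path = Path(rdata_path)
    out_dir = Path(out_dir)
    if not rdata_path.exists():
        raise FileNotFoundError(rdata_path)
    out_dir.mkdir(parents=True, exist_ok=True)
    with tempfile.TemporaryDirectory() as tmp:
        script = Path(tmp) / "dump.R"
        script.write_text(_R_DUMP_SCRIPT)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script), str(rdata_path), tmp],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise RuntimeError(
                f"R conversion of {rdata_path} failed:\n{proc.stderr.strip()}"
            )
        written: list[Path] = []
        for csv in sorted(Path(tmp).glob("*.csv")):
            mat = np.loadtxt(csv, delimiter=",", ndmin=2)
            if mat.shape[1] % 3 != 0:
                raise RuntimeError(f"{csv.name}: column count {mat.shape[1]} not a multiple of 3")
            n = mat.shape[1] // 3
            frames = mat.reshape(mat.shape[0], n, 3)
            atoms = [
                AtomRecord(atom_index=i, atom_name="CA", residue_number=i + 1,
                           residue_name="GLY", chain_id="A")
                for i in range(n)
            ]
            ens = TrajectoryEnsemble(atoms=atoms, frames=frames, label=csv.stem)
            out = out_dir / f"{csv.stem}.pdb"
            write_ensemble(ens, out)
            written.append(out)
    if not written:
        raise RuntimeError(f"no coordinate matrices extracted from {rdata_path}")
    manifest = out_dir / "conversion_manifest.json"
    manifest.write_text(json.dumps({"source": str(rdata_path), "files": [p.name for p in written]}, indent=2))
    return written
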
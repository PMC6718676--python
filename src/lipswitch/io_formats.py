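"""On-disk contracts: multi-model PDB trajectories, sidecar TSV tables, trace CSV.

The trajectory interchange dialect is multi-model PDB (``MODEL``/``ENDMDL``
blocks sharing one topology).  Two chains are used throughout the package:

* ``P`` — the protein,
* ``M`` — the membrane (headgroup pseudo-atoms named ``N``).

Leaflet membership is stored explicitly, never inferred at read time: on disk
it lives in the B-factor column (0 = none, 1 = upper, 2 = lower) or in a
sidecar TSV (columns ``atom_id``, ``leaflet``).  In memory it is an integer
annotation ``leaflet`` on the :class:`biotite.structure.AtomArrayStack`.

Units: coordinates in Å, trajectory time in ps, trace time in s.  Frame
indexing is 0-based; residue numbering is 1-based (PDB convention).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "LEAFLET_NONE",
    "LEAFLET_UPPER",
    "LEAFLET_LOWER",
    "PROTEIN_CHAIN",
    "MEMBRANE_CHAIN",
    "FormatError",
    "Trajectory",
    "ParamTable",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_leaflet_tsv",
    "write_leaflet_tsv",
    "read_param_tsv",
    "write_param_tsv",
    "read_trace_csv",
    "write_trace_csv",
]

LEAFLET_NONE = 0
LEAFLET_UPPER = 1
LEAFLET_LOWER = 2

_LEAFLET_NAMES = {LEAFLET_NONE: "none", LEAFLET_UPPER: "upper", LEAFLET_LOWER: "lower"}
_LEAFLET_CODES = {v: k for k, v in _LEAFLET_NAMES.items()}

PROTEIN_CHAIN = "P"
MEMBRANE_CHAIN = "M"


class FormatError(ValueError):
    """A file violates the on-disk contract (inconsistent models, bad fields)."""


@dataclass
class Trajectory:
    """Ordered frames of coordinates sharing one topology.

    Parameters
    ----------
    stack
        ``AtomArrayStack`` with annotations ``chain_id`` (``P``/``M``),
        ``atom_name``, ``res_id``, ``res_name`` and the integer ``leaflet``.
    frame_interval_ps
        Time between consecutive frames, in ps.
    """

    stack: struc.AtomArrayStack
    frame_interval_ps: float = 100.0

    def __post_init__(self) -> None:
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")
        if "leaflet" not in self.stack.get_annotation_categories():
            self.stack.set_annotation(
                "leaflet", np.zeros(self.stack.array_length(), dtype=int)
            )

    @property
    def n_frames(self) -> int:
        return self.stack.stack_depth()

    @property
    def n_atoms(self) -> int:
        return self.stack.array_length()

    @property
    def duration_ns(self) -> float:
        """Span covered by the frames: n_frames x frame_interval, in ns."""
        return self.n_frames * self.frame_interval_ps / 1000.0

    @property
    def times_ns(self) -> np.ndarray:
        """Time stamp of each frame (frame i is at i x interval), in ns."""
        return np.arange(self.n_frames) * self.frame_interval_ps / 1000.0

    def frame(self, i: int) -> struc.AtomArray:
        return self.stack[i]

    def protein_mask(self) -> np.ndarray:
        return self.stack.chain_id == PROTEIN_CHAIN

    def membrane_mask(self) -> np.ndarray:
        return self.stack.chain_id == MEMBRANE_CHAIN


@dataclass
class ParamTable:
    """Per-atom nonbonded parameters: charge (e), sigma (Å), epsilon (kcal/mol)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"charge", "sigma", "epsilon"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"parameter table missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise FormatError("duplicate atom_id in parameter table")
        if (self.table["epsilon"] < 0).any():
            raise ValueError("epsilon must be >= 0")
        if (self.table["sigma"] <= 0).any():
            raise ValueError("sigma must be > 0")

    def lookup(self, atom_ids: np.ndarray) -> pd.DataFrame:
        """Rows for the given atom ids; raises listing any id without a row."""
        atom_ids = np.asarray(atom_ids)
        present = self.table.index
        missing = [int(a) for a in atom_ids if a not in present]
        if missing:
            raise KeyError(f"no parameters for atom_ids {missing[:10]}")
        return self.table.loc[atom_ids]


def _precheck_models(lines: list[str]) -> None:
    """Validate model atom-count consistency and coordinate fields.

    A cheap pass over the raw lines so contract violations are reported with
    the model number / line number, independent of the backend parser.
    """
    counts: list[int] = []
    current: int | None = None
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            current = 0
        elif rec.startswith("ENDMDL"):
            counts.append(current or 0)
            current = None
        elif rec in ("ATOM  ", "HETATM"):
            if current is not None:
                current += 1
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise FormatError(
                        f"unparseable coordinate at line {lineno}: {line.rstrip()!r}"
                    ) from None
    if counts and len(set(counts)) > 1:
        bad = next(i + 1 for i, c in enumerate(counts) if c != counts[0])
        raise FormatError(
            f"inconsistent atom count across models: model {bad} has "
            f"{counts[bad - 1]} atoms, model 1 has {counts[0]}"
        )


def read_multimodel_pdb(
    path,
    frame_interval_ps: float = 100.0,
    leaflet_tsv=None,
) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    The topology is taken from the first model.  Leaflet flags are read from
    the B-factor column unless ``leaflet_tsv`` names a sidecar table, which
    then takes precedence.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    # tolerate trailing whitespace / blank lines
    lines = [ln.rstrip() for ln in lines if ln.strip()]
    _precheck_models(lines)
    pdb = PDBFile.read(io.StringIO("\n".join(lines) + "\n"))
    try:
        stack = pdb.get_structure(extra_fields=["b_factor"])
    except Exception as exc:  # pragma: no cover - backstop after precheck
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    leaflet = np.rint(stack.b_factor[0] if stack.b_factor.ndim == 2 else stack.b_factor)
    stack.set_annotation("leaflet", leaflet.astype(int))
    traj = Trajectory(stack, frame_interval_ps=frame_interval_ps)
    if leaflet_tsv is not None:
        apply_leaflet_tsv(traj, leaflet_tsv)
    _validate_leaflets(traj)
    return traj


def _validate_leaflets(traj: Trajectory) -> None:
    bad = set(traj.stack.leaflet) - set(_LEAFLET_NAMES)
    if bad:
        raise FormatError(f"unknown leaflet codes {sorted(bad)}")
    prot = traj.protein_mask()
    if np.any(traj.stack.leaflet[prot] != LEAFLET_NONE):
        raise FormatError("protein atoms must carry leaflet 'none'")


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-model PDB with leaflet flags in B-factor."""
    stack = traj.stack.copy()
    stack.set_annotation("b_factor", stack.leaflet.astype(float))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


def read_leaflet_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"atom_id", "leaflet"} <= set(df.columns):
        raise FormatError("leaflet sidecar needs columns atom_id, leaflet")
    codes = df["leaflet"].map(_LEAFLET_CODES)
    if codes.isna().any():
        bad = df.loc[codes.isna(), "leaflet"].unique()
        raise FormatError(f"unknown leaflet labels {list(bad)}")
    return pd.Series(codes.values, index=df["atom_id"].values)


def apply_leaflet_tsv(traj: Trajectory, path) -> None:
    codes = read_leaflet_tsv(path)
    atom_ids = np.arange(1, traj.n_atoms + 1)
    leaflet = np.zeros(traj.n_atoms, dtype=int)
    for aid, code in codes.items():
        if not 1 <= aid <= traj.n_atoms:
            raise FormatError(f"sidecar atom_id {aid} outside 1..{traj.n_atoms}")
        leaflet[aid - 1] = code
    del atom_ids
    traj.stack.set_annotation("leaflet", leaflet)


def write_leaflet_tsv(traj: Trajectory, path) -> None:
    df = pd.DataFrame(
        {
            "atom_id": np.arange(1, traj.n_atoms + 1),
            "leaflet": [_LEAFLET_NAMES[c] for c in traj.stack.leaflet],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_param_tsv(path) -> ParamTable:
    """Read a TSV with columns atom_id, charge, sigma, epsilon."""
    df = pd.read_csv(path, sep="\t")
    if "atom_id" not in df.columns:
        raise FormatError("parameter table needs an atom_id column")
    return ParamTable(df.set_index("atom_id"))


def write_param_tsv(params: ParamTable, path) -> None:
    params.table.rename_axis("atom_id").reset_index().to_csv(path, sep="\t", index=False)


def read_trace_csv(path):
    """Read a fluorescence trace CSV into a :class:`~lipswitch.kinetics.KineticTrace`.

    Leading ``#`` comment lines may carry calibration metadata as
    ``key=value`` pairs (keys: F0, Fmax, Fmin, t_inject, t_protein).  The body
    is two numeric columns, time (s) and intensity (a.u.).
    """
    from .kinetics import KineticTrace

    meta: dict[str, float] = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                text = stripped.lstrip("#").strip()
                if "=" in text:
                    key, _, value = text.partition("=")
                    try:
                        meta[key.strip()] = float(value)
                    except ValueError:
                        raise FormatError(f"bad metadata line: {stripped!r}") from None
            else:
                body.append(stripped)
    df = pd.read_csv(io.StringIO("\n".join(body)))
    if df.shape[1] < 2:
        raise FormatError("trace CSV needs two columns (time, intensity)")
    time = df.iloc[:, 0].to_numpy(float)
    intensity = df.iloc[:, 1].to_numpy(float)
    if np.any(np.diff(time) <= 0):
        raise FormatError("trace time column must be strictly increasing")
    return KineticTrace(
        time=time,
        F=intensity,
        F0=meta.get("F0"),
        Fmax=meta.get("Fmax"),
        Fmin=meta.get("Fmin"),
        t_inject=meta.get("t_inject"),
        t_protein=meta.get("t_protein"),
    )


def write_trace_csv(trace, path) -> None:
    with open(path, "w") as fh:
        for key in ("F0", "Fmax", "Fmin", "t_inject", "t_protein"):
            value = getattr(trace, key)
            if value is not None:
                fh.write(f"# {key}={value}\n")
        fh.write("time_s,intensity\n")
        for t, f in zip(trace.time, trace.F):
            fh.write(f"{t},{f}\n")
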
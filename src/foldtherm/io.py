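"""Structure, time-series and replica-exchange bookkeeping I/O.

File dialects
-------------
* Cα structures: PDB, one :class:`Structure` per MODEL.  Only Cα atoms are
  retained on reading; alternate locations resolve to the highest-occupancy
  conformer (ties: the first one printed).  Residue numbers are kept exactly
  as printed in the file.
* Time series: plain tab-separated text.  Each series block starts with
  header lines ``#temperature=``, ``#quantity=``, ``#dt=`` followed by a
  ``time_ns<TAB>value`` column header and the data rows.  A file may hold
  several blocks.  Values are written with 17 significant digits so that
  write/read round trips are lossless.
* Replica records: tab-separated ``time_index  replica  temperature`` rows;
  at every time index the temperature assignment must be a bijection
  between replicas and the temperature ladder.

Units: Å, kcal/mol, ns, K throughout (stated in the headers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


class FormatError(ValueError):
    """Raised when an input file does not follow the documented dialect."""


class ConsistencyError(ValueError):
    """Raised when replica records violate the replica/temperature bijection."""


@dataclass(frozen=True)
class Structure:
    """A labeled set of Cα positions.

    Parameters
    ----------
    residue_numbers : array of int
        1-based residue numbers, strictly increasing, as printed in the
        source file.
    coords : array, shape (n, 3)
        Cα positions in Å.
    label : str
        Free-form identifier (model number, cluster id, ...).
    """

    residue_numbers: np.ndarray
    coords: np.ndarray
    label: str = ""

    def __post_init__(self):
        rn = np.asarray(self.residue_numbers, dtype=int)
        xyz = np.asarray(self.coords, dtype=float)
        if xyz.ndim != 2 or xyz.shape[1] != 3 or xyz.shape[0] != rn.shape[0]:
            raise ValueError("coords must be (n, 3) matching residue_numbers")
        if rn.size and np.any(np.diff(rn) <= 0):
            raise ValueError("residue_numbers must be strictly increasing")
        if not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "residue_numbers", rn)
        object.__setattr__(self, "coords", xyz)

    def __len__(self) -> int:
        return self.coords.shape[0]

    def subset(self, residues: Sequence[int]) -> np.ndarray:
        """Coordinates of the given residue numbers, in the order requested."""
        idx = self.indices_of(residues)
        return self.coords[idx]

    def indices_of(self, residues: Sequence[int]) -> np.ndarray:
        lookup = {int(r): i for i, r in enumerate(self.residue_numbers)}
        missing = [int(r) for r in residues if int(r) not in lookup]
        if missing:
            raise ValueError(f"residues not present in structure: {missing}")
        return np.array([lookup[int(r)] for r in residues], dtype=int)


@dataclass
class TemperatureSeries:
    """Time-ordered scalar samples tagged with a temperature.

    ``quantity`` is a free tag; the conventional ones are ``energy``
    (kcal/mol), ``rmsd`` (Å), ``rg`` (Å) and ``coordinate``
    (dimensionless toy-model coordinate).
    """

    temperature: float
    dt: float
    values: np.ndarray
    quantity: str = "energy"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.size

    @property
    def time(self) -> np.ndarray:
        """Sample times in ns, starting at 0."""
        return np.arange(self.values.size) * self.dt


@dataclass
class ReplicaRecords:
    """Replica ↔ temperature assignment over time.

    Row ``k``: at time index ``time_index[k]`` replica ``replica[k]`` was
    simulating at ``temperature[k]``.
    """

    time_index: np.ndarray
    replica: np.ndarray
    temperature: np.ndarray

    def __post_init__(self):
        self.time_index = np.asarray(self.time_index, dtype=int)
        self.replica = np.asarray(self.replica, dtype=int)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if not (self.time_index.shape == self.replica.shape == self.temperature.shape):
            raise ValueError("record columns must have equal length")


# ---------------------------------------------------------------------------
# PDB I/O (Cα subset) via biotite
# ---------------------------------------------------------------------------

def read_ca_pdb(path) -> list[Structure]:
    """Read a (possibly multi-model) PDB file, keeping only Cα atoms.

    Returns one :class:`Structure` per MODEL.  Alternate locations keep the
    highest-occupancy conformer (ties: first).
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(altloc="occupancy")
    except Exception as exc:  # malformed records
        raise FormatError(f"{path}: cannot parse PDB file: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    mask = stack.atom_name == "CA"
    if not np.any(mask):
        raise FormatError(f"{path}: no Cα atoms found")
    out = []
    for i in range(stack.stack_depth()):
        model = stack[i][mask]
        out.append(
            Structure(
                residue_numbers=model.res_id,
                coords=model.coord,
                label=f"{path.stem}:model{i + 1}",
            )
        )
    return out


def write_ca_pdb(structures: Sequence[Structure], path) -> None:
    """Write structures as a (multi-)model Cα-only PDB file.

    All structures must share the same residue numbering (PDB MODELs must
    contain the same atoms).  Coordinates survive a round trip to the PDB
    fixed-width precision of 1e-3 Å.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if not structures:
        raise ValueError("no structures to write")
    first = structures[0]
    for s in structures[1:]:
        if not np.array_equal(s.residue_numbers, first.residue_numbers):
            raise ValueError("multi-model output requires identical residue numbering")

    n = len(first)
    arrays = []
    for s in structures:
        arr = struc.AtomArray(n)
        arr.coord = s.coords
        arr.res_id = s.residue_numbers
        arr.res_name = np.full(n, "ALA")
        arr.atom_name = np.full(n, "CA")
        arr.element = np.full(n, "C")
        arr.chain_id = np.full(n, "A")
        arr.hetero = np.zeros(n, dtype=bool)
        arrays.append(arr)
    pdb = PDBFile()
    pdb.set_structure(struc.stack(arrays))
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Tab-separated series tables
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("temperature", "quantity", "dt")


def write_series_table(series: Sequence[TemperatureSeries] | TemperatureSeries, path) -> None:
    """Write one or more series as tab-separated blocks (see module docs)."""
    if isinstance(series, TemperatureSeries):
        series = [series]
    if not series:
        raise ValueError("no series to write")
    with open(path, "w") as fh:
        for s in series:
            fh.write(f"#temperature={float(s.temperature)!r}\n")
            fh.write(f"#quantity={s.quantity}\n")
            fh.write(f"#dt={float(s.dt)!r}\n")
            for key, val in sorted(s.meta.items()):
                if isinstance(val, (str, int, float, bool)):
                    fh.write(f"#meta:{key}={val!r}\n")
            fh.write("time_ns\tvalue\n")
            for t, v in zip(s.time, s.values):
                fh.write(f"{t:.10g}\t{v:.17g}\n")


def read_series_table(path) -> list[TemperatureSeries]:
    """Read all series blocks from a tab-separated table file."""
    import ast

    path = Path(path)
    blocks: list[TemperatureSeries] = []
    header: dict = {}
    meta: dict = {}
    values: list[float] = []

    def flush():
        if not header and not values:
            return
        for key in _REQUIRED_KEYS:
            if key not in header:
                raise FormatError(f"{path}: series block missing required header '#{key}='")
        blocks.append(
            TemperatureSeries(
                temperature=float(header["temperature"]),
                dt=float(header["dt"]),
                values=np.array(values, dtype=float),
                quantity=header["quantity"],
                meta=dict(meta),
            )
        )

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if values:  # a new block begins
                    flush()
                    header, meta, values = {}, {}, []
                key, _, val = line[1:].partition("=")
                if key.startswith("meta:"):
                    try:
                        meta[key[5:]] = ast.literal_eval(val)
                    except (ValueError, SyntaxError):
                        meta[key[5:]] = val
                else:
                    header[key] = val
                continue
            if line.startswith("time_ns"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            try:
                values.append(float(parts[1]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad value {parts[1]!r}") from exc
    flush()
    if not blocks:
        raise FormatError(f"{path}: no series blocks found")
    return blocks


def write_replica_records(records: ReplicaRecords, path) -> None:
    with open(path, "w") as fh:
        fh.write("time_index\treplica\ttemperature\n")
        for t, r, temp in zip(records.time_index, records.replica, records.temperature):
            fh.write(f"{t}\t{r}\t{temp:.17g}\n")


def read_replica_records(path) -> ReplicaRecords:
    data = np.loadtxt(path, skiprows=1, ndmin=2)
    if data.size == 0:
        raise FormatError(f"{path}: no replica records")
    return ReplicaRecords(
        time_index=data[:, 0].astype(int),
        replica=data[:, 1].astype(int),
        temperature=data[:, 2],
    )


# ---------------------------------------------------------------------------
# Replica demultiplexing
# ---------------------------------------------------------------------------

def demux_replicas(
    records: ReplicaRecords, raw: dict[int, TemperatureSeries]
) -> dict[float, TemperatureSeries]:
    """Reassemble per-temperature series from per-replica series.

    ``raw`` maps replica id to the series that replica produced (sample
    ``t`` of a replica was generated while it held whatever temperature the
    records assign to it at time index ``t``).  The output series at ladder
    temperature ``T`` concatenates, in time order, the samples of whichever
    replica held ``T``.  Total sample count is conserved.
    """
    replica_ids = sorted(raw)
    n_rep = len(replica_ids)
    n_time = min(len(raw[r]) for r in replica_ids)

    order = np.lexsort((records.replica, records.time_index))
    ti = records.time_index[order]
    rep = records.replica[order]
    temp = records.temperature[order]

    ladder = np.unique(records.temperature)
    if ladder.size != n_rep:
        raise ConsistencyError(
            f"{ladder.size} distinct temperatures for {n_rep} replicas"
        )
    temp_pos = {t: k for k, t in enumerate(ladder)}

    out_values = np.full((n_rep, n_time), np.nan)
    for t0 in range(n_time):
        sel = slice(t0 * n_rep, (t0 + 1) * n_rep)
        if (
            ti[sel].size != n_rep
            or np.any(ti[sel] != t0)
            or len(set(rep[sel])) != n_rep
            or len({temp_pos.get(x) for x in temp[sel]}) != n_rep
        ):
            raise ConsistencyError(
                f"replica/temperature assignment is not a bijection at time index {t0}"
            )
        for r, T in zip(rep[sel], temp[sel]):
            out_values[temp_pos[T], t0] = raw[int(r)].values[t0]

    any_raw = raw[replica_ids[0]]
    return {
        float(T): TemperatureSeries(
            temperature=float(T),
            dt=any_raw.dt,
            values=out_values[k],
            quantity=any_raw.quantity,
            meta={"demuxed": True},
        )
        for k, T in enumerate(ladder)
    }
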
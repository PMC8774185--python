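"""Reading and writing 1D SAS curves and atomic coordinate files.

Curves are 3-column ASCII (Q [1/A], I(Q), sigma) in the dialect used by
SASBDB depositions: comment/header lines start with '#' or are simply not
parseable as numbers, columns are whitespace- or comma-separated, and a
sigma column may be absent.  Atomic models come from PDB-format text.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = [
    "ScatteringCurve",
    "AtomicModel",
    "read_curve",
    "write_curve",
    "read_atomic_model",
    "parse_pdb_text",
]

# elements that occur in protein + heme structures, for symbol validation
# and for inference from atom names
_KNOWN_ELEMENTS = {
    "H", "D", "C", "N", "O", "S", "P", "FE", "ZN", "CU", "MG", "MN", "CA",
    "NA", "K", "CL", "F", "BR", "I", "SE", "NI", "CO", "MO",
}
_TWO_LETTER = {"FE", "ZN", "CU", "MG", "MN", "NA", "CL", "BR", "SE", "NI",
               "CO", "MO"}
_WATER_RESNAMES = {"HOH", "DOD", "WAT", "H2O", "D2O", "TIP", "SOL"}


@dataclass
class ScatteringCurve:
    """A reduced 1D small-angle scattering dataset.

    Parameters
    ----------
    q : ndarray
        Momentum transfer, 1/A, strictly increasing and positive.
    intensity : ndarray
        Differential scattering cross-section per point.  Units are
        arbitrary-but-consistent (cm^-1 for absolute-scale data).
        Non-positive values are legal: background-subtracted data dip
        below zero and log-space operations must mask them, not fail.
    sigma : ndarray or None
        1-sigma uncertainty per point; None means unit weights downstream.
    label : str
        Free-text sample label.
    concentration : float or None
        Protein concentration in mg/mL, if known.
    pd_value : float or None
        Solution pD (pH-meter reading + 0.4 in D2O), if known.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    label: str = ""
    concentration: Optional[float] = None
    pd_value: Optional[float] = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or self.intensity.shape != self.q.shape:
            raise ValueError("q and intensity must be 1D arrays of equal length")
        if self.q.size and self.q[0] <= 0:
            raise ValueError("all q must be > 0")
        dq = np.diff(self.q)
        if np.any(dq <= 0):
            i = int(np.argmax(dq <= 0)) + 1
            raise ValueError(f"q must be strictly increasing; row {i} violates this")
        if self.sigma is not None:
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma < 0):
                raise ValueError("sigma must be >= 0")
        if not np.all(np.isfinite(self.q)) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("q and intensity must be finite")
        if self.q.size and self.q[-1] > 5.0:
            warnings.warn(
                f"max Q = {self.q[-1]:.3g} exceeds 5 /A; data may be in 1/nm "
                "(no conversion applied)",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return self.q.size

    @property
    def weights(self) -> np.ndarray:
        """Least-squares weights 1/sigma^2 (unit weights when sigma absent)."""
        if self.sigma is None:
            return np.ones_like(self.q)
        w = np.zeros_like(self.sigma)
        ok = self.sigma > 0
        w[ok] = 1.0 / self.sigma[ok] ** 2
        if np.any(~ok):  # zero-sigma points get the median weight
            w[~ok] = np.median(w[ok]) if np.any(ok) else 1.0
        return w

    def crop(self, q_min: float = 0.0, q_max: float = np.inf) -> "ScatteringCurve":
        """Return the sub-curve with q_min <= q <= q_max."""
        m = (self.q >= q_min) & (self.q <= q_max)
        return replace(
            self,
            q=self.q[m],
            intensity=self.intensity[m],
            sigma=None if self.sigma is None else self.sigma[m],
        )


@dataclass
class AtomicModel:
    """Labeled atomic coordinates (one structure, possibly multi-chain).

    Arrays are parallel, one entry per atom.  ``assembly`` records whether
    the model was reduced to a single protomer ("monomer"), kept whole
    ("dimer") or passed through as deposited ("asis").
    """

    element: np.ndarray          # uppercase symbols, e.g. "C", "FE"
    atom_name: np.ndarray        # PDB atom names, e.g. "CA", "ND1"
    res_name: np.ndarray
    res_seq: np.ndarray          # int residue sequence numbers
    chain_id: np.ndarray
    coords: np.ndarray           # (n, 3) float, Angstrom
    occupancy: np.ndarray = field(default=None)  # type: ignore[assignment]
    assembly: str = "asis"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.occupancy is None:
            self.occupancy = np.ones(len(self.coords))
        for name in ("element", "atom_name", "res_name", "res_seq", "chain_id"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atomic coordinates must be finite")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def chains(self) -> list:
        seen: dict = {}
        for c in self.chain_id:
            seen.setdefault(c, None)
        return list(seen)

    def select(self, mask: np.ndarray) -> "AtomicModel":
        return AtomicModel(
            element=self.element[mask],
            atom_name=self.atom_name[mask],
            res_name=self.res_name[mask],
            res_seq=self.res_seq[mask],
            chain_id=self.chain_id[mask],
            coords=self.coords[mask],
            occupancy=self.occupancy[mask],
            assembly=self.assembly,
        )


def _tokenize(line: str) -> list:
    return line.replace(",", " ").split()


def read_curve(path: Union[str, Path], dialect: str = "auto") -> ScatteringCurve:
    """Read a 1D SAS curve from SASBDB-style ASCII.

    Any line whose first token does not parse as a number is skipped
    (headers, comments, trailing metadata).  2-column files yield a curve
    with ``sigma=None``; a third column is taken as sigma.  ``dialect``
    accepts "auto", "sasbdb" or "csv" — all use the same tolerant parser
    (whitespace and comma separation are both accepted).

    Raises
    ------
    ValueError
        On fewer than 5 data rows, or non-monotonic Q (the error names the
        first offending data row).
    """
    if dialect not in ("auto", "sasbdb", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    label, conc, pd_value = path.stem, None, None
    rows = []
    ncol = None
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                meta = stripped.lstrip("#").strip()
                low = meta.lower()
                if low.startswith("label:"):
                    label = meta.split(":", 1)[1].strip()
                elif low.startswith("concentration"):
                    try:
                        conc = float(meta.split(":", 1)[1].split()[0])
                    except (ValueError, IndexError):
                        pass
                elif low.startswith("pd:"):
                    try:
                        pd_value = float(meta.split(":", 1)[1])
                    except ValueError:
                        pass
                continue
            toks = _tokenize(stripped)
            try:
                vals = [float(t) for t in toks[:3]]
            except ValueError:
                continue  # header row such as "Q I err"
            if len(vals) < 2:
                continue
            if ncol is None:
                ncol = len(vals)
            rows.append(vals[:ncol])
    if len(rows) < 5:
        raise ValueError(f"{path}: found only {len(rows)} data rows (need >= 5)")
    arr = np.array([r + [np.nan] * (3 - len(r)) for r in rows])
    q, inten = arr[:, 0], arr[:, 1]
    sigma = arr[:, 2] if ncol == 3 and np.all(np.isfinite(arr[:, 2])) else None
    dq = np.diff(q)
    if np.any(dq <= 0):
        i = int(np.argmax(dq <= 0)) + 1
        raise ValueError(f"{path}: Q not strictly increasing at data row {i + 1} "
                         f"(q={q[i]:.6g} after {q[i - 1]:.6g})")
    return ScatteringCurve(q=q, intensity=inten, sigma=sigma, label=label,
                           concentration=conc, pd_value=pd_value)


def write_curve(curve: ScatteringCurve, path: Union[str, Path]) -> None:
    """Write a curve as '#'-headed 3-column (or 2-column) ASCII.

    The header records label, concentration and pD so that
    :func:`read_curve` round-trips the metadata.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# label: {curve.label}\n")
        if curve.concentration is not None:
            fh.write(f"# concentration: {curve.concentration:g} mg/mL\n")
        if curve.pd_value is not None:
            fh.write(f"# pD: {curve.pd_value:g}\n")
        if curve.sigma is None:
            fh.write("# Q(1/A)  I(Q)\n")
            for q, i in zip(curve.q, curve.intensity):
                fh.write(f"{q:.9e} {i:.9e}\n")
        else:
            fh.write("# Q(1/A)  I(Q)  sigma\n")
            for q, i, s in zip(curve.q, curve.intensity, curve.sigma):
                fh.write(f"{q:.9e} {i:.9e} {s:.9e}\n")


def _infer_element(atom_name: str, res_name: str, serial: int) -> str:
    """Fall back to the PDB atom-name convention when the element column
    is blank: the element occupies columns 13-14 of the name field."""
    name = atom_name.strip()
    if not name:
        raise ValueError(f"atom serial {serial}: empty atom name")
    head = name[:2].upper()
    if head in _TWO_LETTER:
        return head
    first = name[0]
    if first.isdigit():  # e.g. "1HB" hydrogens
        first = name[1]
    sym = first.upper()
    if sym in _KNOWN_ELEMENTS:
        return sym
    raise ValueError(
        f"atom serial {serial}: cannot infer element from name {atom_name!r} "
        f"in residue {res_name!r}"
    )


def parse_pdb_text(text: str, assembly: str = "asis") -> AtomicModel:
    """Parse ATOM/HETATM records from PDB-format text.

    assembly:
      "monomer" — first protein chain plus HETATM groups (heme) sharing its
                  chain id;
      "dimer"   — all chains;
      "asis"    — all chains (alias of dimer for deposited dimers).
    Waters are always dropped; hydrogens are kept if present.
    """
    if assembly not in ("monomer", "dimer", "asis"):
        raise ValueError(f"unknown assembly {assembly!r}")
    element, atom_name, res_name, res_seq, chain_id, coords, occ = \
        [], [], [], [], [], [], []
    for line in io.StringIO(text):
        if not (line.startswith("ATOM") or line.startswith("HETATM")):
            continue
        try:
            serial = int(line[6:11])
        except ValueError:
            serial = -1
        name = line[12:16].strip()
        altloc = line[16:17]
        if altloc not in (" ", "", "A", "1"):
            continue  # keep only the first alternate location
        resn = line[17:20].strip()
        if resn in _WATER_RESNAMES:
            continue
        chain = line[21:22].strip() or "A"
        try:
            resi = int(line[22:26])
        except ValueError:
            resi = 0
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        try:
            o = float(line[54:60])
        except (ValueError, IndexError):
            o = 1.0
        elem = line[76:78].strip().upper() if len(line) > 76 else ""
        if elem not in _KNOWN_ELEMENTS:
            elem = _infer_element(name, resn, serial)
        element.append(elem)
        atom_name.append(name)
        res_name.append(resn)
        res_seq.append(resi)
        chain_id.append(chain)
        coords.append((x, y, z))
        occ.append(o)
    if not coords:
        raise ValueError("no ATOM/HETATM records found")
    model = AtomicModel(
        element=np.array(element), atom_name=np.array(atom_name),
        res_name=np.array(res_name), res_seq=np.array(res_seq, dtype=int),
        chain_id=np.array(chain_id), coords=np.array(coords, dtype=float),
        occupancy=np.array(occ, dtype=float), assembly=assembly,
    )
    if assembly == "monomer":
        first_chain = model.chain_id[0]
        model = model.select(model.chain_id == first_chain)
        model.assembly = "monomer"
    return model


def read_atomic_model(path: Union[str, Path], assembly: str = "asis") -> AtomicModel:
    """Read an :class:`AtomicModel` from a PDB file (see :func:`parse_pdb_text`)."""
    with open(path) as fh:
        return parse_pdb_text(fh.read(), assembly=assembly)
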
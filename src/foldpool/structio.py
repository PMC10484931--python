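"""Read and write CA-trace protein models in PDB format.

All downstream scoring in this package is alpha-carbon based, so only CA
``ATOM`` records are consumed and emitted.  Per-residue confidence (pLDDT
on the 0-100 scale) travels in the B-factor column, the convention used
by AlphaFold-family predictors.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StructureModel",
    "PDBParseError",
    "ChainNotFoundError",
    "read_model",
    "write_model",
    "global_plddt",
]

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted as a CA-trace model."""


class ChainNotFoundError(KeyError):
    """Raised when the requested chain is absent from the file."""


@dataclass(frozen=True)
class StructureModel:
    """One monomer model: sequence, CA coordinates and per-residue confidence.

    Parameters
    ----------
    model_id, target_id : str
        Identifiers of the model and of the prediction target it belongs to.
    chain_id : str
        Single-character chain identifier.
    sequence : str
        One-letter amino-acid string of length N (unknown residues as ``X``).
    residue_numbers : ndarray of int, shape (N,)
        Strictly increasing author residue numbers; all cross-model residue
        correspondence in this package is by residue number.
    ca_coords : ndarray of float, shape (N, 3)
        CA coordinates in Angstrom.
    plddt : ndarray of float, shape (N,)
        Per-residue confidence in [0, 100].
    source_tag : str
        Provenance: a sampling-method name, ``assembly_extracted``,
        ``refined`` or ``grafted``.
    """

    model_id: str
    target_id: str
    chain_id: str
    sequence: str
    residue_numbers: np.ndarray
    ca_coords: np.ndarray
    plddt: np.ndarray
    source_tag: str = "default"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residue_numbers", np.asarray(self.residue_numbers, dtype=int)
        )
        object.__setattr__(
            self, "ca_coords", np.asarray(self.ca_coords, dtype=float)
        )
        object.__setattr__(self, "plddt", np.asarray(self.plddt, dtype=float))
        n = len(self.sequence)
        if n < 1:
            raise ValueError("a StructureModel must contain at least one residue")
        if self.residue_numbers.shape != (n,):
            raise ValueError("residue_numbers length must match sequence length")
        if self.ca_coords.shape != (n, 3):
            raise ValueError("ca_coords must have shape (N, 3)")
        if self.plddt.shape != (n,):
            raise ValueError("plddt length must match sequence length")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.plddt < 0.0) or np.any(self.plddt > 100.0):
            raise ValueError("plddt values must lie in [0, 100]")
        if np.any(np.diff(self.residue_numbers) <= 0):
            raise ValueError("residue_numbers must be strictly increasing")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def with_(self, **changes) -> "StructureModel":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def read_model(path: str | Path, chain: Optional[str] = None) -> StructureModel:
    """Read one chain of a PDB file as a :class:`StructureModel`.

    ``chain`` defaults to the first chain encountered.  Residues without a
    CA atom are skipped with a logged warning; for altloc'd CA atoms the
    first one is kept.  Insertion codes are rejected.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0 or len(st[0]) == 0:
        raise PDBParseError(f"{path}: no ATOM records found")
    model = st[0]
    chain_names = [ch.name for ch in model]
    if chain is None:
        chain = chain_names[0]
    if chain not in chain_names:
        raise ChainNotFoundError(
            f"{path}: chain {chain!r} not found (have {chain_names})"
        )

    records: list[tuple[int, str, np.ndarray, float]] = []
    for res in model[chain]:
        if res.het_flag != "A":
            continue
        icode = res.seqid.icode
        if icode not in (" ", "", "\x00"):
            raise PDBParseError(
                f"{path}: insertion code {icode!r} at residue "
                f"{res.seqid.num} is not supported"
            )
        ca = None
        for atom in res:
            if atom.name == "CA":
                ca = atom  # first altloc kept
                break
        if ca is None:
            logger.warning(
                "%s: residue %s %d in chain %s has no CA atom; skipped",
                path, res.name, res.seqid.num, chain,
            )
            continue
        one = THREE_TO_ONE.get(res.name, "X")
        records.append(
            (res.seqid.num, one, np.array([ca.pos.x, ca.pos.y, ca.pos.z]), ca.b_iso)
        )
    if not records:
        raise PDBParseError(f"{path}: chain {chain} has no CA atoms")
    records.sort(key=lambda r: r[0])
    nums = [r[0] for r in records]
    if len(set(nums)) != len(nums):
        raise PDBParseError(f"{path}: duplicate residue numbers in chain {chain}")
    return StructureModel(
        model_id=path.stem,
        target_id=path.stem,
        chain_id=chain,
        sequence="".join(r[1] for r in records),
        residue_numbers=np.array(nums),
        ca_coords=np.vstack([r[2] for r in records]),
        plddt=np.array([r[3] for r in records]),
    )


def write_model(model: StructureModel, path: str | Path) -> None:
    """Write a CA-only PDB file (fixed columns per wwPDB 3.3).

    The B-factor column (61-66) carries pLDDT to two decimals; coordinates
    are written to three decimals, so a read/write round trip is exact to
    format precision.
    """
    path = Path(path)
    lines = []
    for i in range(model.n_residues):
        res3 = ONE_TO_THREE.get(model.sequence[i], "UNK")
        x, y, z = model.ca_coords[i]
        lines.append(
            f"ATOM  {i + 1:5d}  CA  {res3:<3s} {model.chain_id}"
            f"{int(model.residue_numbers[i]):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{model.plddt[i]:6.2f}"
            f"           C"
        )
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def global_plddt(model: StructureModel) -> float:
    """Arithmetic mean of per-residue pLDDT (the global confidence score)."""
    if model.n_residues < 1:
        raise ValueError("empty model")
    return float(np.mean(model.plddt))
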
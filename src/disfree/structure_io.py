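"""Reading and writing single-chain structure models and multi-model ensembles.

The rest of the package consumes two coordinate views per residue: the Cα
position and an *interaction center* (side-chain heavy-atom centroid when
side-chain atoms are present, Cα otherwise).  Input author numbering is
discarded: residues are renumbered 1..N in chain order, because the
free-energy model is positional and numbering gaps would corrupt loop
lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from Bio.PDB.StructureBuilder import StructureBuilder
from Bio.Data.PDBData import protein_letters_3to1

__all__ = [
    "StructureModel",
    "Ensemble",
    "StructureError",
    "read_ensemble",
    "write_ensemble",
]

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


class StructureError(ValueError):
    """Malformed, inconsistent or unsupported structure input."""


@dataclass
class StructureModel:
    """One conformation of a single chain.

    Attributes
    ----------
    model_id : str
        Identifier of the model (MODEL serial number for PDB input).
    aa : list of str
        One-letter amino-acid codes, index ``i`` is residue ``i + 1``.
    ca : (N, 3) ndarray
        Cα coordinates in Å.
    center : (N, 3) ndarray
        Interaction-center coordinates in Å (side-chain centroid, or Cα
        for glycine / missing side chains).
    """

    model_id: str
    aa: list[str]
    ca: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        n = len(self.aa)
        if self.ca.shape != (n, 3) or self.center.shape != (n, 3):
            raise StructureError(
                f"model {self.model_id!r}: coordinate arrays must be ({n}, 3)"
            )
        if not (np.isfinite(self.ca).all() and np.isfinite(self.center).all()):
            raise StructureError(f"model {self.model_id!r}: non-finite coordinates")

    @property
    def n(self) -> int:
        return len(self.aa)

    @property
    def residues(self) -> Iterator[tuple[int, str, np.ndarray, np.ndarray]]:
        """Iterate ``(index, aa, ca, center)`` with 1-based indices."""
        for i in range(self.n):
            yield i + 1, self.aa[i], self.ca[i], self.center[i]

    def subset(self, indices: Sequence[int]) -> "StructureModel":
        """Restrict to the given 1-based residue indices (renumbered)."""
        idx = np.asarray(sorted(indices), dtype=int) - 1
        return StructureModel(
            model_id=self.model_id,
            aa=[self.aa[i] for i in idx],
            ca=self.ca[idx],
            center=self.center[idx],
        )


@dataclass
class Ensemble:
    """A set of models of the same single-chain sequence."""

    sequence: str
    models: list[StructureModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for m in self.models:
            if m.n != n:
                raise StructureError(
                    f"model {m.model_id!r} has {m.n} residues, sequence has {n}"
                )
            if "".join(m.aa) != self.sequence:
                raise StructureError(
                    f"model {m.model_id!r} amino-acid codes disagree with sequence"
                )

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_models(self) -> int:
        return len(self.models)


def _model_from_chain(chain, model_id: str) -> StructureModel:
    aa: list[str] = []
    cas: list[np.ndarray] = []
    centers: list[np.ndarray] = []
    for res in chain:
        if res.id[0] != " ":  # HETATM / water
            continue
        if "CA" not in res:
            raise StructureError(
                f"model {model_id!r}: residue {res.id[1]} has no CA atom"
            )
        ca = res["CA"].get_coord().astype(float)
        side = [
            a.get_coord()
            for a in res.get_atoms()
            if a.get_name() not in _BACKBONE and a.element != "H"
        ]
        center = np.mean(side, axis=0) if side else ca
        aa.append(protein_letters_3to1.get(res.get_resname(), "X"))
        cas.append(ca)
        centers.append(np.asarray(center, dtype=float))
    if not aa:
        raise StructureError(f"model {model_id!r}: no amino-acid residues found")
    model = StructureModel(model_id=model_id, aa=aa, ca=np.array(cas),
                           center=np.array(centers))
    d = np.linalg.norm(np.diff(model.ca, axis=0), axis=1)
    if model.n > 1 and ((d <= 2.0) | (d >= 5.0)).any():
        warnings.warn(
            f"model {model_id!r}: consecutive CA distances outside (2, 5) Å",
            stacklevel=3,
        )
    return model


def read_ensemble(path: str | Path) -> Ensemble:
    """Read a single-chain, possibly multi-model, PDB file.

    A file without MODEL records is treated as one model.  Only the first
    chain is accepted; additional chains raise :class:`StructureError`.
    Residues are renumbered 1..N in chain order.
    """
    path = Path(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise StructureError(f"{path}: malformed PDB record: {exc}") from exc
    models: list[StructureModel] = []
    for mdl in structure:
        chains = list(mdl)
        if len(chains) > 1:
            raise StructureError(
                f"{path}: model {mdl.serial_num} has {len(chains)} chains; "
                "only single-chain input is supported"
            )
        models.append(_model_from_chain(chains[0], model_id=str(mdl.serial_num)))
    if not models:
        raise StructureError(f"{path}: no models found")
    n = models[0].n
    for m in models:
        if m.n != n:
            raise StructureError(
                f"{path}: model {m.model_id} has {m.n} residues, "
                f"model {models[0].model_id} has {n}"
            )
    return Ensemble(sequence="".join(models[0].aa), models=models)


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file.

    MODEL/ENDMDL records are always emitted, even for one model, so that a
    round trip is unambiguous.  Interaction centers that differ from Cα are
    written as a pseudo side-chain atom ("CB") at the centroid position, so
    reading the file back reproduces both coordinate views to PDB precision
    (3 decimals).
    """
    if ensemble.n_models == 0:
        raise StructureError("cannot write an ensemble with no models")
    builder = StructureBuilder()
    builder.init_structure("ens")
    for k, m in enumerate(ensemble.models):
        builder.init_model(k, k + 1)
        builder.init_chain("A")
        builder.init_seg("    ")
        serial = 1
        for i, aa, ca, center in m.residues:
            builder.init_residue(_1TO3.get(aa, "UNK"), " ", i, " ")
            builder.init_atom("CA", ca, 0.0, 1.0, " ", " CA ", serial, "C")
            serial += 1
            if not np.allclose(ca, center, atol=1e-4):
                builder.init_atom("CB", center, 0.0, 1.0, " ", " CB ", serial, "C")
                serial += 1
    out = builder.get_structure()
    for k, mdl in enumerate(out):
        mdl.serial_num = k + 1
    pdbio = PDBIO(use_model_flag=1)
    pdbio.set_structure(out)
    pdbio.save(str(path))
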
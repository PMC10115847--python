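"""Predicted protein structures: parsing, fragment stitching, contacts.

Structures arrive as PDB or mmCIF files from a structure-prediction pipeline,
with the per-residue confidence (pLDDT, 0-100) stored in the B-factor field
of deposited models.  Long proteins are predicted as overlapping fragments;
:func:`stitch_fragment_models` combines them into a single model, choosing
the higher-confidence fragment per overlap residue.  Because independently
predicted fragments need not share a coordinate frame, stitched models track
a frame id per residue and :func:`structural_contacts` never pairs residues
across un-coregistered frames.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from epivep.graph import PartnerGraph


@dataclasses.dataclass
class StructureModel:
    """Per-residue C-alpha trace with confidence.

    positions are 1-based and strictly increasing; ``frame`` groups residues
    whose coordinates share a frame (all zero for single-file models);
    ``n_skipped`` counts residues omitted for lacking a C-alpha atom.
    """

    protein: str
    positions: np.ndarray          # (n,) int
    coords: np.ndarray             # (n, 3) float, Å
    plddt: np.ndarray              # (n,) float, 0-100
    frame: Optional[np.ndarray] = None   # (n,) int
    n_skipped: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        if self.frame is None:
            self.frame = np.zeros(len(self.positions), dtype=int)
        else:
            self.frame = np.asarray(self.frame, dtype=int)
        if len(self.positions) == 0:
            raise ValueError("no residues")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("residue positions must be strictly increasing")
        if self.coords.shape != (len(self.positions), 3):
            raise ValueError("coords must be (n_residues, 3)")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def length(self) -> int:
        """Protein length implied by the last modeled position."""
        return int(self.positions[-1])

    def plddt_at(self, position: int) -> Optional[float]:
        idx = np.searchsorted(self.positions, position)
        if idx < len(self.positions) and self.positions[idx] == position:
            return float(self.plddt[idx])
        return None


def read_structure_model(path, protein: Optional[str] = None) -> StructureModel:
    """Read the first polymer chain of a PDB or mmCIF file.

    One entry per residue with a C-alpha atom; pLDDT taken from the C-alpha
    B-factor.  For disordered (altloc) atoms the parser's selected conformer
    (first altloc) is used.  mmCIF files are read with label (not auth)
    residue numbering.
    """
    from Bio.PDB import MMCIFParser, PDBParser

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PDBConstructionWarning on odd files
        if path.suffix.lower() in (".cif", ".mmcif"):
            parser = MMCIFParser(QUIET=True, auth_residues=False)
        else:
            parser = PDBParser(QUIET=True)
        structure = parser.get_structure(protein or path.stem, str(path))

    models = list(structure)
    if not models:
        raise ValueError(f"no residues in {path}")
    chains = list(models[0])
    if not chains:
        raise ValueError(f"no residues in {path}")
    chain = chains[0]

    positions, coords, plddt = [], [], []
    skipped = 0
    for residue in chain:
        if residue.id[0].strip():  # heteroatoms / waters
            continue
        if "CA" not in residue:
            skipped += 1
            continue
        ca = residue["CA"]
        positions.append(residue.id[1])
        coords.append(ca.get_coord())
        plddt.append(ca.get_bfactor())
    if not positions:
        raise ValueError(f"no residues with C-alpha atoms in {path}")
    if skipped:
        warnings.warn(f"{path.name}: {skipped} residues without C-alpha omitted")
    order = np.argsort(positions)
    return StructureModel(
        protein=protein or path.stem,
        positions=np.asarray(positions)[order],
        coords=np.asarray(coords)[order],
        plddt=np.asarray(plddt)[order],
        n_skipped=skipped,
    )


#: Overlap C-alpha RMSD below which two fragments are treated as sharing a
#: coordinate frame.  Above it, cross-fragment contacts are suppressed.
COREGISTRATION_RMSD = 2.0


def stitch_fragment_models(fragments: Sequence[StructureModel]) -> StructureModel:
    """Combine overlapping fragment models into one full-length model.

    Fragments must cover contiguous, pairwise-overlapping ranges.  In each
    overlap the residue comes from the fragment with the higher pLDDT there.
    Consecutive fragments whose overlap C-alpha RMSD (after index alignment)
    is below :data:`COREGISTRATION_RMSD` are assigned the same frame id;
    otherwise the next fragment opens a new frame and a warning is issued.
    """
    if not fragments:
        raise ValueError("no fragments")
    if len(fragments) == 1:
        return fragments[0]

    frags = sorted(fragments, key=lambda f: int(f.positions[0]))
    frame_of_frag = [0]
    for prev, nxt in zip(frags, frags[1:]):
        if int(nxt.positions[0]) > int(prev.positions[-1]) + 1:
            raise ValueError(
                f"fragments not contiguous: gap between {int(prev.positions[-1])} "
                f"and {int(nxt.positions[0])}"
            )
        shared = np.intersect1d(prev.positions, nxt.positions)
        same_frame = False
        if len(shared) > 0:
            a = prev.coords[np.searchsorted(prev.positions, shared)]
            b = nxt.coords[np.searchsorted(nxt.positions, shared)]
            rmsd = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
            same_frame = rmsd < COREGISTRATION_RMSD
        if same_frame:
            frame_of_frag.append(frame_of_frag[-1])
        else:
            frame_of_frag.append(frame_of_frag[-1] + 1)
            warnings.warn(
                f"fragments over {int(prev.positions[0])}-{int(prev.positions[-1])} and "
                f"{int(nxt.positions[0])}-{int(nxt.positions[-1])} are not co-registered; "
                "contacts across this boundary will be suppressed"
            )

    # per-position winner by pLDDT
    best: dict[int, tuple[float, int, int]] = {}  # pos -> (plddt, frag_idx, row)
    for fi, frag in enumerate(frags):
        for row, pos in enumerate(frag.positions):
            pos = int(pos)
            cand = (float(frag.plddt[row]), fi, row)
            if pos not in best or cand[0] > best[pos][0]:
                best[pos] = cand
    positions = np.array(sorted(best), dtype=int)
    coords = np.array([frags[best[p][1]].coords[best[p][2]] for p in positions])
    plddt = np.array([best[p][0] for p in positions])
    frame = np.array([frame_of_frag[best[p][1]] for p in positions], dtype=int)
    return StructureModel(
        protein=frags[0].protein,
        positions=positions,
        coords=coords,
        plddt=plddt,
        frame=frame,
        n_skipped=sum(f.n_skipped for f in frags),
    )


def structural_contacts(
    model: StructureModel,
    cutoff_angstrom: float = 11.0,
    min_separation: int = 0,
) -> PartnerGraph:
    """All residue pairs with C-alpha distance strictly below the cutoff.

    The default 11 Å reflects the distance at which a partner-label model is
    most balanced between sensitivity and specificity; pairs at exactly the
    cutoff are excluded.  ``min_separation`` optionally drops trivially close
    sequence neighbours (|i - j| <= min_separation).  Pairs spanning
    un-coregistered stitched frames are never emitted.
    """
    if cutoff_angstrom <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff_angstrom}")
    if len(model) < 2:
        return PartnerGraph(protein=model.protein)

    tree = cKDTree(model.coords)
    graph = PartnerGraph(protein=model.protein)
    for a, b in tree.query_pairs(r=cutoff_angstrom):
        if model.frame[a] != model.frame[b]:
            continue
        i, j = int(model.positions[a]), int(model.positions[b])
        if abs(i - j) <= min_separation:
            continue
        # KDTree uses <=; enforce the strict inequality
        d = float(np.linalg.norm(model.coords[a] - model.coords[b]))
        if d < cutoff_angstrom:
            graph.add(i, j, kind="structural")
    return graph
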
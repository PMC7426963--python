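"""Reading, validating and preparing antibody Fab chains from PDB files.

The comparison pipeline works on *prepared* chains: one polypeptide chain,
backbone atoms only (plus the single side-chain atom used for hinge-angle
anchors), residues renumbered sequentially 1..n so that the free and bound
forms of an identical antibody can be compared position by position.  This
module owns that preparation step and the selection filters applied before
any geometry is computed:

* crystallographic resolution must be better than ~3 Å,
* the backbone must be continuous (C(i)-N(i+1) within peptide-bond range),
* free and bound chains must share 100% sequence identity (checked by the
  pipeline via :func:`sequence_identity`).

Parsing is delegated to :mod:`gemmi`; only the first model is used,
heteroatoms and waters are dropped, and for alternate locations the
highest-occupancy conformer is kept (ties broken toward altloc 'A').
"""

from __future__ import annotations

import logging
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import gemmi
import numpy as np

from .errors import (
    DiscontinuityError,
    FetchError,
    MissingChainError,
    ParseError,
)

logger = logging.getLogger(__name__)

ChainType = Literal["heavy", "light_kappa", "light_lambda"]

#: Backbone atoms used for superposition and deviation metrics.  O is kept
#: when present in both structures being compared; side chains are excluded
#: throughout except for the anchor atoms below.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Side-chain reference atom per anchor residue type (Cys, Ser, Arg, Gln).
SIDECHAIN_ANCHOR_ATOMS = {"C": "SG", "S": "OG", "R": "CZ", "Q": "CD"}

#: Maximum C(i)-N(i+1) distance still counted as a peptide bond.  A formed
#: bond sits near 1.33 Å; a chain break in a crystal structure jumps to
#: several Å, so 2.5 Å separates the two regimes robustly.
PEPTIDE_BOND_CUTOFF = 2.5

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@dataclass
class ResidueRecord:
    """One amino-acid residue with backbone (and anchor side-chain) coords."""

    seq_index: int                    # sequential position, 1-based
    author_number: str                # original numbering incl. insertion code
    aa: str                           # one-letter code, 'X' if nonstandard
    backbone_coords: dict[str, np.ndarray]   # N/CA/C and O when present
    sidechain_anchor: np.ndarray | None = None
    sidechain_atom: str | None = None

    def copy(self) -> "ResidueRecord":
        return ResidueRecord(
            seq_index=self.seq_index,
            author_number=self.author_number,
            aa=self.aa,
            backbone_coords={k: v.copy() for k, v in self.backbone_coords.items()},
            sidechain_anchor=None if self.sidechain_anchor is None else self.sidechain_anchor.copy(),
            sidechain_atom=self.sidechain_atom,
        )


@dataclass
class StructureRecord:
    """A parsed structure: raw chains in author numbering, first model only."""

    entry_id: str
    resolution: float | None
    chains: dict[str, list[ResidueRecord]]
    model_index: int = 0
    n_incomplete_dropped: int = 0


@dataclass
class ResolutionVerdict:
    passed: bool
    resolution: float | None
    warning: bool = False          # set when resolution is absent

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


@dataclass
class ChainModel:
    """A prepared, continuous antibody chain with sequential numbering."""

    chain_id: str
    chain_type: ChainType
    residues: list[ResidueRecord]
    source_entry: str = ""

    def __post_init__(self) -> None:
        for i, res in enumerate(self.residues, start=1):
            if res.seq_index != i:
                raise ValueError(
                    f"seq_index must be contiguous 1..n; got {res.seq_index} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def residue(self, seq_index: int) -> ResidueRecord:
        return self.residues[seq_index - 1]

    def copy(self) -> "ChainModel":
        return ChainModel(
            chain_id=self.chain_id,
            chain_type=self.chain_type,
            residues=[r.copy() for r in self.residues],
            source_entry=self.source_entry,
        )


def parse_structure(pdb_text: str, entry_id: str = "XXXX") -> StructureRecord:
    """Parse PDB-format text into a :class:`StructureRecord`.

    Only the first model is read.  Waters and heteroatoms are dropped, as are
    residues missing any of the N/CA/C backbone atoms (they cannot take part
    in backbone metrics and would silently distort them).  For alternate
    locations the highest-occupancy atom wins; on a tie the lexicographically
    first altloc (i.e. 'A') is kept.

    Raises
    ------
    ParseError
        If the text contains no usable ATOM records.
    """
    try:
        structure = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{entry_id}: unreadable PDB text: {exc}") from exc
    if len(structure) == 0:
        raise ParseError(f"{entry_id}: no models in PDB text")

    resolution = structure.resolution if structure.resolution > 0 else None
    model = structure[0]
    chains: dict[str, list[ResidueRecord]] = {}
    n_dropped = 0
    for chain in model:
        residues: list[ResidueRecord] = []
        for res in chain:
            if res.het_flag != "A":
                continue
            info = gemmi.find_tabulated_residue(res.name)
            if info is not None and not info.is_amino_acid():
                continue
            aa = _THREE_TO_ONE.get(res.name.upper(), "X")
            atoms = _select_altlocs(res)
            if any(name not in atoms for name in ("N", "CA", "C")):
                n_dropped += 1
                continue
            backbone = {
                name: atoms[name] for name in BACKBONE_ATOMS if name in atoms
            }
            anchor_name = SIDECHAIN_ANCHOR_ATOMS.get(aa)
            anchor = atoms.get(anchor_name) if anchor_name else None
            icode = res.seqid.icode.strip()
            residues.append(
                ResidueRecord(
                    seq_index=len(residues) + 1,
                    author_number=f"{res.seqid.num}{icode}",
                    aa=aa,
                    backbone_coords=backbone,
                    sidechain_anchor=anchor,
                    sidechain_atom=anchor_name if anchor is not None else None,
                )
            )
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise ParseError(f"{entry_id}: no amino-acid ATOM records found")
    all_coords = np.concatenate(
        [v for c in chains.values() for r in c for v in r.backbone_coords.values()]
    )
    if not np.all(np.isfinite(all_coords)):
        raise ParseError(f"{entry_id}: non-finite coordinates")
    return StructureRecord(
        entry_id=entry_id,
        resolution=resolution,
        chains=chains,
        model_index=0,
        n_incomplete_dropped=n_dropped,
    )


def _select_altlocs(res: gemmi.Residue) -> dict[str, np.ndarray]:
    """Resolve alternate locations: highest occupancy, tie -> first altloc."""
    best: dict[str, tuple[float, str, np.ndarray]] = {}
    for atom in res:
        pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
        altloc = atom.altloc if atom.altloc != "\x00" else ""
        occ = float(atom.occ)
        prev = best.get(atom.name)
        # occupancies come through float32; compare with a small tolerance
        if prev is None or occ > prev[0] + 1e-6 or (
            abs(occ - prev[0]) <= 1e-6 and altloc < prev[1]
        ):
            best[atom.name] = (occ, altloc, pos)
    return {name: pos for name, (_, _, pos) in best.items()}


def check_resolution(
    record: StructureRecord, max_resolution: float = 3.0
) -> ResolutionVerdict:
    """Apply the resolution filter (default: better than ~3 Å).

    Structures without a reported resolution pass with a warning flag, so
    the decision (and the missing value) can be logged by the caller.
    """
    if record.resolution is None:
        logger.warning("%s: no resolution in header; filter passes by default",
                       record.entry_id)
        return ResolutionVerdict(passed=True, resolution=None, warning=True)
    return ResolutionVerdict(
        passed=record.resolution <= max_resolution,
        resolution=record.resolution,
    )


def extract_chain(
    record: StructureRecord,
    chain_id: str,
    chain_type: ChainType,
    span: tuple[int, int] | None = None,
) -> ChainModel:
    """Extract one chain, renumber it sequentially and verify continuity.

    ``span`` is an inclusive 1-based window in *author order* (useful for
    selecting a single Fab copy out of a multi-copy asymmetric unit); it is
    applied before renumbering.

    Raises
    ------
    MissingChainError
        If ``chain_id`` is absent.
    DiscontinuityError
        If any consecutive C(i)-N(i+1) distance exceeds the peptide-bond
        cutoff — the rule under which discontinuous entries are excluded
        from analysis.
    """
    if chain_id not in record.chains:
        raise MissingChainError(
            f"{record.entry_id}: chain '{chain_id}' not found "
            f"(available: {sorted(record.chains)})"
        )
    raw = record.chains[chain_id]
    if span is not None:
        lo, hi = span
        raw = raw[lo - 1 : hi]
    if not raw:
        raise MissingChainError(
            f"{record.entry_id}:{chain_id}: selected window is empty"
        )
    residues = []
    for i, res in enumerate(raw, start=1):
        r = res.copy()
        r.seq_index = i
        residues.append(r)
    for i in range(len(residues) - 1):
        c = residues[i].backbone_coords["C"]
        n = residues[i + 1].backbone_coords["N"]
        gap = float(np.linalg.norm(c - n))
        if gap > PEPTIDE_BOND_CUTOFF:
            raise DiscontinuityError(
                f"{record.entry_id}:{chain_id}: chain break between residues "
                f"{residues[i].author_number} and {residues[i + 1].author_number} "
                f"(C-N distance {gap:.2f} Å > {PEPTIDE_BOND_CUTOFF} Å)"
            )
    return ChainModel(
        chain_id=chain_id,
        chain_type=chain_type,
        residues=residues,
        source_entry=record.entry_id,
    )


def sequence_identity(a: ChainModel | str, b: ChainModel | str) -> float:
    """Percent identity (as a fraction) from a global alignment.

    Scoring is match=1, mismatch=0, gap=0: the alignment maximises the
    number of matched positions and, among those optima, uses the fewest
    alignment columns (so a substitution counts as one aligned column, not
    a gap pair).  Identity = matches / alignment columns.  The pipeline
    requires 1.0 for a valid free/bound couple.
    """
    sa = a.sequence if isinstance(a, ChainModel) else a
    sb = b.sequence if isinstance(b, ChainModel) else b
    if not sa or not sb:
        raise ValueError("sequence_identity requires non-empty chains")
    n, m = len(sa), len(sb)
    # DP over (max matches, -columns), lexicographic
    NEG = (-1, 0)
    prev = [(0, -j) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(0, -i)] + [NEG] * m
        ai = sa[i - 1]
        for j in range(1, m + 1):
            diag = (prev[j - 1][0] + (1 if ai == sb[j - 1] else 0),
                    prev[j - 1][1] - 1)
            up = (prev[j][0], prev[j][1] - 1)
            left = (cur[j - 1][0], cur[j - 1][1] - 1)
            cur[j] = max(diag, up, left)
        prev = cur
    matches, neg_cols = prev[m]
    return matches / (-neg_cols)


def fetch_pdb(
    accession: str,
    cache_dir: str | Path | None = None,
    timeout: float = 30.0,
) -> str:
    """Download a PDB entry from the RCSB (convenience; cached on disk).

    Analysis never requires this — all tests run on local or synthetic
    structures — but real couples are most easily pulled by accession.
    """
    accession = accession.strip().upper()
    if len(accession) != 4 or not accession.isalnum():
        raise FetchError(f"'{accession}' is not a valid 4-character PDB code")
    if cache_dir is not None:
        cached = Path(cache_dir) / f"{accession}.pdb"
        if cached.exists():
            return cached.read_text()
    url = f"https://files.rcsb.org/download/{accession}.pdb"
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode("utf-8", errors="replace")
    except OSError as exc:
        raise FetchError(f"could not fetch {accession} from {url}: {exc}") from exc
    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        (Path(cache_dir) / f"{accession}.pdb").write_text(text)
    return text


def chain_to_pdb(
    chains: Sequence[ChainModel],
    entry_id: str = "PREP",
    resolution: float | None = None,
) -> str:
    """Serialise prepared chains as minimal PDB text (sequential numbering)."""
    lines = [f"HEADER    PREPARED FAB CHAINS                             {entry_id:<4}"]
    if resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {resolution:4.2f} ANGSTROMS.")
    serial = 1
    for chain in chains:
        for res in chain.residues:
            resname = ONE_TO_THREE.get(res.aa, "UNK")
            atoms: list[tuple[str, np.ndarray]] = [
                (name, res.backbone_coords[name])
                for name in BACKBONE_ATOMS
                if name in res.backbone_coords
            ]
            if res.sidechain_anchor is not None and res.sidechain_atom:
                atoms.append((res.sidechain_atom, res.sidechain_anchor))
            for name, xyz in atoms:
                element = name[0]
                # columns: 13-16 atom name, 17 altloc, 18-20 resname,
                # 22 chain id, 23-26 resseq, 31- coordinates
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s} {resname:>3s} "
                    f"{chain.chain_id[0]}{res.seq_index:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
                )
                serial += 1
        lines.append(
            f"TER   {serial:5d}      {ONE_TO_THREE.get(chain.residues[-1].aa, 'UNK'):>3s} "
            f"{chain.chain_id[0]}{len(chain.residues):4d}"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_chain_pdb(
    chains: Sequence[ChainModel],
    path: str | Path,
    entry_id: str = "PREP",
    resolution: float | None = None,
) -> Path:
    """Write prepared chains to a PDB file for inspection / round-tripping."""
    path = Path(path)
    path.write_text(chain_to_pdb(chains, entry_id=entry_id, resolution=resolution))
    return path
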
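"""Taxonomic hierarchy and genome manifest.

The tree follows the NCBI taxdump dialect (pipe-delimited ``nodes.dmp`` /
``names.dmp`` records) restricted to the seven-level ladder
superkingdom > phylum > class > order > family > genus > species; any other
rank string maps to ``no_rank`` and such nodes are traversed transparently.
Genomes live outside the tree in a manifest (accession, taxid,
type-material flag) so one tree can serve many datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "RANK_LADDER",
    "TaxonNode",
    "TaxonomyTree",
    "GenomeManifestEntry",
    "TaxonomyFormatError",
    "load_taxonomy",
    "write_taxonomy",
    "descendant_taxa",
    "genomes_of",
    "load_manifest",
    "write_manifest",
]

RANK_LADDER = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
_KNOWN_RANKS = set(RANK_LADDER) | {"no_rank"}


class TaxonomyFormatError(ValueError):
    """Malformed taxonomy dump (cycle, orphan parent, duplicate taxid)."""


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    name: str
    rank: str
    parent_taxid: int


@dataclass(frozen=True)
class GenomeManifestEntry:
    genome_accession: str
    taxid: int
    is_type_material: bool


class TaxonomyTree:
    """Rooted taxonomy with an explicit children index.

    The root is the node that is its own parent (taxid 1 in NCBI dumps).
    Children lists are kept sorted by taxid so every traversal is
    deterministic.
    """

    def __init__(self, nodes: Iterable[TaxonNode]) -> None:
        self.nodes: dict[int, TaxonNode] = {}
        for node in nodes:
            if node.taxid in self.nodes:
                raise TaxonomyFormatError(f"duplicate taxid {node.taxid}")
            self.nodes[node.taxid] = node
        roots = [n.taxid for n in self.nodes.values() if n.parent_taxid == n.taxid]
        if len(roots) != 1:
            raise TaxonomyFormatError(f"expected exactly one root, found {roots}")
        self.root = roots[0]
        self.children: dict[int, list[int]] = {t: [] for t in self.nodes}
        for node in self.nodes.values():
            if node.taxid == self.root:
                continue
            if node.parent_taxid not in self.nodes:
                raise TaxonomyFormatError(
                    f"taxid {node.taxid} has missing parent {node.parent_taxid}"
                )
            self.children[node.parent_taxid].append(node.taxid)
        for kids in self.children.values():
            kids.sort()
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            t = stack.pop()
            seen.add(t)
            stack.extend(self.children[t])
        unreachable = set(self.nodes) - seen
        if unreachable:
            raise TaxonomyFormatError(
                f"nodes unreachable from root (cycle?): {sorted(unreachable)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonomyTree) and self.nodes == other.nodes

    def name(self, taxid: int) -> str:
        return self.nodes[taxid].name

    def rank(self, taxid: int) -> str:
        return self.nodes[taxid].rank

    def subtree(self, taxid: int) -> Iterable[int]:
        """All taxids of the subtree rooted at ``taxid`` (preorder,
        children in ascending-taxid order)."""
        if taxid not in self.nodes:
            raise KeyError(f"unknown taxid {taxid}")
        stack = [taxid]
        while stack:
            t = stack.pop()
            yield t
            stack.extend(reversed(self.children[t]))


def _split_dump_line(line: str) -> list[str]:
    # taxdump records are "field<TAB>|<TAB>field..." terminated by "<TAB>|"
    return [f.strip("\t ") for f in line.rstrip("\n").rstrip("\t|").split("|")]


def load_taxonomy(nodes_source, names_source) -> TaxonomyTree:
    """Build a tree from taxdump-dialect ``nodes`` and ``names`` records.

    ``nodes_source``/``names_source`` are paths or open text handles.
    Only 'scientific name' rows of the names file are used; unknown rank
    strings map to ``no_rank``.
    """

    def _lines(source):
        if hasattr(source, "read"):
            return source.read().splitlines()
        with open(source) as fh:
            return fh.read().splitlines()

    names: dict[int, str] = {}
    for line in _lines(names_source):
        if not line.strip():
            continue
        fields = _split_dump_line(line)
        if len(fields) >= 4 and fields[3] != "scientific name":
            continue
        names[int(fields[0])] = fields[1]

    nodes = []
    for line in _lines(nodes_source):
        if not line.strip():
            continue
        fields = _split_dump_line(line)
        taxid, parent = int(fields[0]), int(fields[1])
        rank = fields[2].replace(" ", "_") if len(fields) > 2 else "no_rank"
        if rank not in _KNOWN_RANKS:
            rank = "no_rank"
        nodes.append(
            TaxonNode(
                taxid=taxid,
                name=names.get(taxid, str(taxid)),
                rank=rank,
                parent_taxid=parent,
            )
        )
    return TaxonomyTree(nodes)


def write_taxonomy(tree: TaxonomyTree, nodes_fh, names_fh) -> None:
    """Emit the tree in the same dump dialect ``load_taxonomy`` reads."""
    for taxid in sorted(tree.nodes):
        node = tree.nodes[taxid]
        rank = node.rank.replace("_", " ")
        nodes_fh.write(f"{node.taxid}\t|\t{node.parent_taxid}\t|\t{rank}\t|\n")
        names_fh.write(f"{node.taxid}\t|\t{node.name}\t|\t\t|\tscientific name\t|\n")


def descendant_taxa(tree: TaxonomyTree, taxid: int, rank: str) -> list[int]:
    """All descendants of ``taxid`` (excluding itself) with the requested
    rank, in deterministic depth-first order."""
    if taxid not in tree:
        raise KeyError(f"unknown taxid {taxid}")
    out = []
    for t in tree.subtree(taxid):
        if t != taxid and tree.rank(t) == rank:
            out.append(t)
    return out


def genomes_of(
    tree: TaxonomyTree,
    manifest: Iterable[GenomeManifestEntry],
    taxid: int,
) -> list[GenomeManifestEntry]:
    """Manifest entries assigned to ``taxid`` or any of its descendants."""
    if taxid not in tree:
        raise KeyError(f"unknown taxid {taxid}")
    member = set(tree.subtree(taxid))
    return [e for e in manifest if e.taxid in member]


def load_manifest(source) -> list[GenomeManifestEntry]:
    """Read a manifest TSV: accession, taxid, type_material (0/1)."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    out = []
    for line in lines:
        if not line.strip() or line.startswith("#") or line.startswith("accession"):
            continue
        acc, taxid, type_flag = line.split("\t")[:3]
        out.append(GenomeManifestEntry(acc, int(taxid), type_flag.strip() == "1"))
    return out


def write_manifest(entries: Iterable[GenomeManifestEntry], fh) -> None:
    fh.write("accession\ttaxid\ttype_material\n")
    for e in entries:
        fh.write(f"{e.genome_accession}\t{e.taxid}\t{int(e.is_type_material)}\n")
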
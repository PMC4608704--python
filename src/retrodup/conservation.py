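"""Cross-species retrocopy conservation from genome-alignment blocks.

Orthology between retrocopies of different species is established through
shared alignment blocks: two loci are orthologous when, projected into
block columns, each covers at least 50% of the other's aligned extent
(reciprocal overlap).  Ortholog groups are connected components of that
relation.  The origin lineage of a group with at least two species is the
named clade at the MRCA of its presence set; a single-species group gets no
origin (a lone occurrence cannot be dated under the two-species rule).

A human retrocopy is *ancestral* when it has an ortholog in at least one
other primate (chimpanzee, gorilla, orangutan, macaque or marmoset), and
*deeply conserved* when present outside Euarchontoglires.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import dendropy

from .core import GenomicInterval, OrthologGroup
from .io_formats import MAFBlock

DEFAULT_PRIMATES = frozenset(
    {"chimpanzee", "gorilla", "orangutan", "macaque", "marmoset"})


class _UnionFind:
    def __init__(self):
        self.parent: Dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _reciprocal_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def map_orthologs(
    blocks: Sequence[MAFBlock],
    retrocopy_loci_by_species: Dict[str, Dict[str, GenomicInterval]],
    min_reciprocal_overlap: float = 0.5,
) -> List[OrthologGroup]:
    """Group retrocopies across species through shared alignment blocks.

    Within each block, every species row is intersected with that species'
    retrocopy loci; loci pairs whose block-column extents overlap
    reciprocally by at least *min_reciprocal_overlap* are linked, and
    groups are the connected components of all links.  A retrocopy hitting
    no block becomes a singleton group.
    """
    uf = _UnionFind()
    all_nodes: Set[Tuple[str, str]] = set()
    for sp, loci in retrocopy_loci_by_species.items():
        for rid in loci:
            all_nodes.add((sp, rid))

    for block in blocks:
        per_species: List[Tuple[Tuple[str, str], Tuple[int, int]]] = []
        for sp, row in block.rows.items():
            loci = retrocopy_loci_by_species.get(sp, {})
            for rid, ivl in loci.items():
                cols = row.columns_for(ivl)
                if cols is not None:
                    per_species.append(((sp, rid), cols))
        for i in range(len(per_species)):
            for j in range(i + 1, len(per_species)):
                (na, ca), (nb, cb) = per_species[i], per_species[j]
                if na[0] == nb[0]:
                    continue  # same species: never orthologs of each other
                if _reciprocal_overlap(ca, cb) >= min_reciprocal_overlap:
                    uf.union(na, nb)

    components: Dict[Tuple[str, str], List[Tuple[str, str]]] = defaultdict(list)
    for node in sorted(all_nodes):
        components[uf.find(node)].append(node)
    groups: List[OrthologGroup] = []
    for n, (root, members) in enumerate(sorted(components.items())):
        loci = {}
        member_map = {}
        for sp, rid in members:
            loci[sp] = retrocopy_loci_by_species[sp][rid]
            member_map[sp] = rid
        rep = min(m[1] for m in members)
        groups.append(OrthologGroup(
            group_id=f"og_{rep}", loci=loci, members=member_map))
    groups.sort(key=lambda g: g.group_id)
    return groups


def _clade_node(tree: dendropy.Tree, species: Sequence[str]):
    taxa = []
    for sp in species:
        taxon = tree.taxon_namespace.get_taxon(sp)
        if taxon is None:
            raise ValueError(f"species not in tree: {sp}")
        taxa.append(taxon)
    if len(taxa) == 1:
        return tree.find_node_with_taxon_label(species[0])
    return tree.mrca(taxa=taxa)


def assign_origin_lineage(group: OrthologGroup,
                          tree: dendropy.Tree) -> Optional[str]:
    """Named lineage in whose ancestor the retroposition occurred: the
    nearest named clade at or above the MRCA of the presence set.

    Single-species groups return None (undatable under the any-two-species
    rule).  Unnamed internal nodes are skipped upward so that e.g. a
    human+chimpanzee pair dates to Hominidae, the finest named lineage
    containing both.
    """
    presence = sorted(group.presence)
    if len(presence) < 2:
        return None
    node = _clade_node(tree, presence)
    while node is not None and not node.label:
        node = node.parent_node
    return node.label if node is not None else None


def is_ancestral(group: OrthologGroup,
                 primate_species: FrozenSet[str] = DEFAULT_PRIMATES,
                 human: str = "human") -> bool:
    """A human retrocopy is ancestral iff an ortholog exists in at least
    one other primate from the configured list."""
    if human not in group.presence:
        raise ValueError("group does not contain the human retrocopy")
    return bool((group.presence - {human}) & primate_species)


def is_deeply_conserved(group: OrthologGroup, tree: dendropy.Tree,
                        inner_clade: str = "Euarchontoglires") -> bool:
    """Presence in at least one species outside *inner_clade* (very
    ancient origin)."""
    node = None
    for nd in tree.preorder_node_iter():
        if nd.label == inner_clade:
            node = nd
            break
    if node is None:
        raise ValueError(f"clade not named in tree: {inner_clade}")
    inner = {leaf.taxon.label for leaf in node.leaf_iter()}
    return bool(group.presence - inner)


def annotate_groups(groups: Sequence[OrthologGroup], tree: dendropy.Tree,
                    primate_species: FrozenSet[str] = DEFAULT_PRIMATES,
                    human: str = "human") -> None:
    """Fill origin clade, ancestral and deep-conservation flags in place."""
    for g in groups:
        g.origin_clade = assign_origin_lineage(g, tree)
        g.ancestral = (human in g.presence
                       and is_ancestral(g, primate_species, human))
        g.deep_conservation = is_deeply_conserved(g, tree)


def summarize_lineage_counts(groups: Sequence[OrthologGroup],
                             tree: dendropy.Tree,
                             human: str = "human"
                             ) -> Dict[str, Dict[str, int]]:
    """Two tallies per named clade: groups whose origin is that clade, and
    the subset whose presence set includes human."""
    names = [nd.label for nd in tree.preorder_node_iter()
             if nd.label and not nd.is_leaf()]
    out = {name: {"origin": 0, "origin_with_human": 0} for name in names}
    for g in groups:
        if g.origin_clade is None or g.origin_clade not in out:
            continue
        out[g.origin_clade]["origin"] += 1
        if human in g.presence:
            out[g.origin_clade]["origin_with_human"] += 1
    return out


def write_groups_tsv(groups: Sequence[OrthologGroup], path) -> None:
    import pandas as pd

    rows = []
    for g in groups:
        rows.append({
            "group_id": g.group_id,
            "members": ";".join(f"{sp}:{rid}" for sp, rid
                                in sorted(g.members.items())),
            "presence": ",".join(sorted(g.presence)),
            "n_species": len(g.presence),
            "origin_clade": g.origin_clade or "NA",
            "ancestral": g.ancestral,
            "deep_conservation": g.deep_conservation,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
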
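"""Discovery of retrocopies absent from the reference genome.

Pipeline: per-individual greedy overlap assembly of unmapped reads ->
cross-individual clustering (CD-HIT-style: 95% identity over 70% of the
shorter sequence) -> per-cluster majority-vote consensus -> exclusion of
consensi matching labelled filter databases (genome patches, alternative
assemblies, contaminants) -> retrocopy calling on the retained consensi ->
localisation of the reference-genome deletion site by anchoring outgroup
flanks.

The assembler and clusterer are deliberately simple, deterministic
algorithms sized for resequencing-scale contigs; the fixed thresholds
(500 bp minimum contig, 95%/70% clustering) are the pipeline's defining
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib

from .core import GenomicInterval

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# contigs and assembly
# ---------------------------------------------------------------------------

@dataclass
class Contig:
    id: str
    sequence: str
    individual: str

    def __len__(self) -> int:
        return len(self.sequence)


def _canonical(seq: str) -> str:
    rc = _revcomp(seq)
    return seq if seq <= rc else rc


def assemble_contigs(reads: Dict[str, str], individual: str,
                     min_overlap_bp: int = 31,
                     min_contig_len: int = 500) -> List[Contig]:
    """Greedy overlap assembly of one individual's reads.

    Reads are sorted lexicographically, then contigs are extended by the
    maximal exact suffix-prefix overlap of at least *min_overlap_bp*
    against unused reads (both strands).  Contigs shorter than
    *min_contig_len* are discarded.  Deterministic for a given read set.
    """
    seqs = sorted(set(reads.values()))
    k = min_overlap_bp
    # index reads by their k-mer prefix, on both strands
    prefix_index: Dict[str, List[int]] = {}
    oriented: List[Tuple[str, int]] = []  # (sequence, read index)
    for idx, s in enumerate(seqs):
        for variant in (s, _revcomp(s)):
            oriented.append((variant, idx))
    oriented.sort()
    for oidx, (s, _) in enumerate(oriented):
        prefix_index.setdefault(s[:k], []).append(oidx)

    used = [False] * len(seqs)

    def extend_right(contig: str) -> str:
        while True:
            best: Optional[Tuple[int, int]] = None  # (overlap, oriented idx)
            max_l = min(len(contig), max(len(s) for s, _ in oriented))
            for L in range(max_l, k - 1, -1):
                window = contig[len(contig) - L:len(contig) - L + k]
                for oidx in prefix_index.get(window, ()):
                    s, ridx = oriented[oidx]
                    if used[ridx] or L >= len(s):
                        continue
                    if contig.endswith(s[:L]):
                        best = (L, oidx)
                        break
                if best:
                    break
            if not best:
                return contig
            L, oidx = best
            s, ridx = oriented[oidx]
            used[ridx] = True
            contig = contig + s[L:]

    contigs: List[Contig] = []
    n = 0
    for idx, seed in enumerate(seqs):
        if used[idx]:
            continue
        used[idx] = True
        contig = extend_right(seed)
        contig = _revcomp(extend_right(_revcomp(contig)))
        if len(contig) >= min_contig_len:
            contigs.append(Contig(f"{individual}_contig{n:04d}",
                                  _canonical(contig), individual))
            n += 1
    return contigs


# ---------------------------------------------------------------------------
# alignment identity helper (used by clustering, consensus and filtering)
# ---------------------------------------------------------------------------

def _best_infix(query: str, target: str) -> Tuple[float, str, dict]:
    """Best infix (query-in-target) alignment over both strands.

    Returns ``(identity, strand, edlib result)`` where identity is
    1 - edits/|query| (floored at 0) for the better strand.
    """
    best = (-1.0, "+", None)
    for strand, q in (("+", query), ("-", _revcomp(query))):
        res = edlib.align(q, target, mode="HW", task="path")
        ident = 1.0 - res["editDistance"] / max(len(q), 1)
        if ident > best[0]:
            best = (ident, strand, res)
    return best


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ContigCluster:
    representative: Contig
    members: List[Contig] = field(default_factory=list)
    consensus_sequence: Optional[str] = None

    @property
    def n_individuals(self) -> int:
        return len({m.individual for m in self.members})

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


def cluster_contigs(contigs: Sequence[Contig],
                    min_identity: float = 0.95,
                    min_coverage_of_shorter: float = 0.70
                    ) -> List[ContigCluster]:
    """Greedy incremental clustering in decreasing length order.

    A contig joins the first existing cluster whose representative aligns
    to it at *min_identity* over at least *min_coverage_of_shorter* of the
    shorter of the two sequences; otherwise it founds a new cluster.
    Deterministic: ties in length break on contig id.
    """
    if not contigs:
        return []
    ordered = sorted(contigs, key=lambda c: (-len(c), c.id))
    clusters: List[ContigCluster] = []
    for c in ordered:
        placed = False
        for cl in clusters:
            rep = cl.representative
            shorter, longer = ((c.sequence, rep.sequence)
                               if len(c) <= len(rep)
                               else (rep.sequence, c.sequence))
            # full-length infix identity first; otherwise accept a trimmed
            # core meeting the identity bar over enough of the shorter seq
            ident, _, res = _best_infix(shorter, longer)
            core_ident, core_cov = _core_identity(res, shorter, longer)
            if ident >= min_identity or (
                    core_ident >= min_identity
                    and core_cov >= min_coverage_of_shorter):
                cl.members.append(c)
                placed = True
                break
        if not placed:
            clusters.append(ContigCluster(representative=c, members=[c]))
    clusters.sort(key=lambda cl: cl.representative.id)
    return clusters


def _core_identity(res: Optional[dict], shorter: str, longer: str
                   ) -> Tuple[float, float]:
    """Identity and coverage of the best-aligned core of the shorter
    sequence, trimming poorly matching ends from the edlib path."""
    if res is None or res.get("cigar") is None:
        return (0.0, 0.0)
    ops = _parse_cigar(res["cigar"])
    # prefix/suffix trimming by best-scoring core (match +1, edit -1)
    events: List[Tuple[int, int]] = []  # (query bases consumed, score delta)
    for length, op in ops:
        if op == "=":
            events.append((length, length))
        elif op in ("X", "I"):  # mismatch / insertion both consume query
            events.append((length, -length))
        else:  # D consumes target only
            events.append((0, -length))
    # Kadane over events
    best_score = cur_score = 0
    best_q = cur_q = 0
    for q, s in events:
        cur_score += s
        cur_q += q
        if cur_score <= 0:
            cur_score, cur_q = 0, 0
        elif cur_score > best_score:
            best_score, best_q = cur_score, cur_q
    if best_q == 0:
        return (0.0, 0.0)
    ident = (best_score + best_q) / (2.0 * best_q)
    return (ident, best_q / len(shorter))


def _parse_cigar(cigar: str) -> List[Tuple[int, str]]:
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((int(num), ch))
            num = ""
    return out


def consensus(cluster: ContigCluster) -> str:
    """Star-alignment majority-vote consensus against the representative.

    Every member is aligned to the representative; per representative
    column the majority base wins, ties resolved toward the
    representative.  Insertions relative to the representative are
    ignored.  Singleton clusters return the representative unchanged.
    """
    rep = cluster.representative.sequence
    if cluster.is_singleton:
        return rep
    votes: List[Dict[str, int]] = [dict() for _ in rep]
    for m in cluster.members:
        seq = m.sequence
        dist_plus = edlib.align(seq, rep, mode="HW")["editDistance"]
        dist_minus = edlib.align(_revcomp(seq), rep,
                                 mode="HW")["editDistance"]
        oriented = seq if dist_plus <= dist_minus else _revcomp(seq)
        res = edlib.align(oriented, rep, mode="HW", task="path")
        if res.get("cigar") is None:
            continue
        rpos = res["locations"][0][0]
        qpos = 0
        for length, op in _parse_cigar(res["cigar"]):
            if op == "=" or op == "X":
                for i in range(length):
                    base = oriented[qpos + i]
                    col = votes[rpos + i]
                    col[base] = col.get(base, 0) + 1
                qpos += length
                rpos += length
            elif op == "I":  # insertion in member; skip
                qpos += length
            elif op == "D":  # member lacks these representative bases
                rpos += length
    out = []
    for i, col in enumerate(votes):
        if not col:
            out.append(rep[i])
            continue
        best_n = max(col.values())
        winners = sorted(b for b, n in col.items() if n == best_n)
        out.append(rep[i] if rep[i] in winners else winners[0])
    return "".join(out)


# ---------------------------------------------------------------------------
# filtering against labelled databases
# ---------------------------------------------------------------------------

def filter_sequences(
    consensi: Dict[str, str],
    filter_dbs: Sequence[Tuple[str, Dict[str, str]]],
    min_identity: float = 0.90,
    min_coverage: float = 0.50,
) -> Tuple[Dict[str, str], Dict[str, str]]:
    """Partition consensi into (retained, filtered-with-label).

    A consensus is filtered when any local alignment to any database
    sequence reaches *min_identity* over at least *min_coverage* of the
    consensus; the recorded label is the first matching database in the
    configured order.
    """
    retained: Dict[str, str] = {}
    filtered: Dict[str, str] = {}
    for cid in sorted(consensi):
        seq = consensi[cid]
        label = None
        for db_label, db in filter_dbs:
            for db_seq in db.values():
                shorter = seq if len(seq) <= len(db_seq) else db_seq
                longer = db_seq if shorter is seq else seq
                _, _, res = _best_infix(shorter, longer)
                ident, cov = _core_identity(res, shorter, longer)
                cov_of_consensus = cov * len(shorter) / len(seq)
                if ident >= min_identity and cov_of_consensus >= min_coverage:
                    label = db_label
                    break
            if label:
                break
        if label:
            filtered[cid] = label
        else:
            retained[cid] = seq
    return retained, filtered


# ---------------------------------------------------------------------------
# deletion-site localisation
# ---------------------------------------------------------------------------

@dataclass
class DeletionSiteCall:
    contig_id: str
    reference_interval: GenomicInterval
    outgroup_interval: GenomicInterval
    left_anchor_bp: int
    right_anchor_bp: int
    insertion_point: bool = False  # zero-length gap (retrocopy in reference)


@dataclass
class NoSite:
    contig_id: str
    reason: str


def _occurrences(needle: str, haystacks: Dict[str, str]
                 ) -> List[Tuple[str, int]]:
    hits: List[Tuple[str, int]] = []
    for chrom in sorted(haystacks):
        seq = haystacks[chrom]
        pos = seq.find(needle)
        while pos != -1:
            hits.append((chrom, pos))
            if len(hits) > 1:
                return hits
            pos = seq.find(needle, pos + 1)
    return hits


def locate_deletion_site(
    contig: Contig,
    outgroup_genome: Dict[str, str],
    reference_genome: Dict[str, str],
    min_anchor_bp: int = 40,
    flank_bp: int = 300,
) -> "DeletionSiteCall | NoSite":
    """Locate where the reference genome lost the contig's sequence.

    The contig is placed in the outgroup genome (best infix alignment over
    both strands).  Each outgroup flank is anchored in the reference by
    the *innermost* unique exact *min_anchor_bp*-mer: windows absent from
    the reference (deleted sequence) are skipped outward, a window hit
    more than once aborts with ``ambiguous_anchor``.  Each anchor is then
    extended inward base-by-base while reference and outgroup agree,
    putting the breakpoints at the first disagreement; the deletion site
    is the reference interval strictly between them.  A zero-length gap
    (the homologous region still present, or a perfectly clean cut) is
    reported insertion-point style as a 1 bp interval.  Breakpoints with
    microhomology can shift inward by the length of the chance match.
    """
    best = None
    for chrom in sorted(outgroup_genome):
        seq = outgroup_genome[chrom]
        ident, strand, res = _best_infix(contig.sequence, seq)
        if best is None or ident > best[0]:
            best = (ident, strand, res, chrom)
    if best is None or best[0] < 0.8:
        return NoSite(contig.id, "not_in_outgroup")
    _, strand, res, og_chrom = best
    og_start, og_end = res["locations"][0]
    og_end += 1  # edlib end is inclusive
    og_seq = outgroup_genome[og_chrom]
    left_flank = og_seq[max(0, og_start - flank_bp):og_start]
    right_flank = og_seq[og_end:og_end + flank_bp]
    if len(left_flank) < min_anchor_bp or len(right_flank) < min_anchor_bp:
        return NoSite(contig.id, "flank_too_short")

    # left anchor: innermost unique window, scanning outward
    left_hit = None
    for off in range(0, len(left_flank) - min_anchor_bp + 1):
        win = left_flank[len(left_flank) - min_anchor_bp - off:
                         len(left_flank) - off]
        hits = _occurrences(win, reference_genome)
        if len(hits) > 1:
            return NoSite(contig.id, "ambiguous_anchor")
        if len(hits) == 1:
            left_hit = (hits[0], off)
            break
    # right anchor: innermost unique window, scanning outward
    right_hit = None
    for off in range(0, len(right_flank) - min_anchor_bp + 1):
        win = right_flank[off:off + min_anchor_bp]
        hits = _occurrences(win, reference_genome)
        if len(hits) > 1:
            return NoSite(contig.id, "ambiguous_anchor")
        if len(hits) == 1:
            right_hit = (hits[0], off)
            break
    if left_hit is None or right_hit is None:
        return NoSite(contig.id, "anchor_not_found")
    ((lc, lpos), loff) = left_hit
    ((rc, rpos), roff) = right_hit
    if lc != rc:
        return NoSite(contig.id, "inconsistent_anchors")
    ref_seq = reference_genome[lc]

    # extend the left anchor rightward while reference == outgroup
    left_end = lpos + min_anchor_bp
    inner = left_flank[len(left_flank) - loff:]  # bases inward of anchor
    k = 0
    while k < len(inner) and left_end + k < len(ref_seq) \
            and ref_seq[left_end + k] == inner[k]:
        k += 1
    left_boundary = left_end + k
    # extend the right anchor leftward
    inner = right_flank[:roff]
    k = 0
    while k < len(inner) and rpos - 1 - k >= 0 \
            and ref_seq[rpos - 1 - k] == inner[len(inner) - 1 - k]:
        k += 1
    right_boundary = rpos - k
    if right_boundary < left_boundary:
        # short overlap = breakpoint microhomology: the flanking bases
        # cannot be attributed to one side; collapse to an insertion point
        if left_boundary - right_boundary <= 20:
            left_boundary = right_boundary
        else:
            return NoSite(contig.id, "inconsistent_anchors")
    og_interval = GenomicInterval(og_chrom, og_start, og_end)
    if right_boundary == left_boundary:
        return DeletionSiteCall(
            contig_id=contig.id,
            reference_interval=GenomicInterval(lc, left_boundary,
                                               left_boundary + 1),
            outgroup_interval=og_interval,
            left_anchor_bp=min_anchor_bp, right_anchor_bp=min_anchor_bp,
            insertion_point=True)
    return DeletionSiteCall(
        contig_id=contig.id,
        reference_interval=GenomicInterval(lc, left_boundary,
                                           right_boundary),
        outgroup_interval=og_interval,
        left_anchor_bp=min_anchor_bp, right_anchor_bp=min_anchor_bp)
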
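"""Independent brute-force oracles used to check the library implementations.

These deliberately use naive data structures (per-base position sets,
all-substring scans, explicit per-strand branches) rather than the interval
arithmetic / reflection tricks of the library, so that agreement between
the two is meaningful.
"""

from __future__ import annotations

from refinery.annotation import AnnotationSet, TranscriptModel

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# poly(A) filter


def brute_has_a_run(seq: str, run_length: int, max_mismatch: int) -> bool:
    """Exhaustive scan of every substring of length >= run_length."""
    n = len(seq)
    for i in range(n):
        for j in range(i + run_length, n + 1):
            if sum(1 for c in seq[i:j] if c != "A") <= max_mismatch:
                return True
    return False


def brute_flag_polyA(t: TranscriptModel, genome: dict, run_length=20, max_mismatch=1, window=30) -> bool:
    if len(t.exons) >= 2:
        return False
    chrom_seq = genome[t.chrom]
    if t.strand == "+":
        win = chrom_seq[t.end : min(t.end + window, len(chrom_seq))]
    else:
        win = naive_revcomp(chrom_seq[max(0, t.start - window) : t.start])
    return brute_has_a_run(win, run_length, max_mismatch)


# ---------------------------------------------------------------------------
# structural classification


def _bases(t: TranscriptModel) -> set[int]:
    return {p for e in t.exons for p in range(e.start, e.end)}


def _junc(t: TranscriptModel) -> list[tuple[int, int]]:
    return [(t.exons[i].end, t.exons[i + 1].start) for i in range(len(t.exons) - 1)]


def _contiguous(sub, full) -> bool:
    if not sub:
        return True
    for i in range(len(full) - len(sub) + 1):
        if full[i : i + len(sub)] == list(sub):
            return True
    return False


def brute_classify(
    query: TranscriptModel,
    reference: AnnotationSet,
    mono_overlap: float = 0.5,
) -> str:
    """Re-derive the class code from first principles with base sets."""
    qb = _bases(query)
    qj = _junc(query)
    ref_ts = [
        (t, g)
        for g in reference.genes
        for t in g.transcripts
        if t.chrom == query.chrom
    ]
    same = [(t, g) for t, g in ref_ts if t.strand == query.strand]
    anti = [(t, g) for t, g in ref_ts if t.strand != query.strand]

    def equal(r):
        rj = _junc(r)
        if qj:
            return rj == qj
        if rj:
            return False
        rb = _bases(r)
        ov = len(qb & rb)
        return ov > 0 and ov >= mono_overlap * min(len(qb), len(rb))

    def contained(r):
        return _contiguous(qj, _junc(r)) and qb <= _bases(r)

    def extends(r):
        rj = _junc(r)
        return len(rj) >= 1 and len(qj) > len(rj) and _contiguous(rj, qj)

    def shares_junction(r):
        return bool(set(qj) & set(_junc(r)))

    def exon_overlap(r):
        return bool(qb & _bases(r))

    def exon_in_intron(r):
        introns = [(r.exons[i].end, r.exons[i + 1].start) for i in range(len(r.exons) - 1)]
        for s, e in introns:
            for ex in query.exons:
                if s <= ex.start and ex.end <= e:
                    return True
        return False

    def gene_in_intron(g):
        gs = min(t.exons[0].start for t in g.transcripts)
        ge = max(t.exons[-1].end for t in g.transcripts)
        q_introns = [(query.exons[i].end, query.exons[i + 1].start) for i in range(len(query.exons) - 1)]
        return any(s <= gs and ge <= e for s, e in q_introns)

    if any(equal(r) for r, _ in same):
        return "="
    if any(contained(r) for r, _ in same):
        return "c"
    if any(extends(r) for r, _ in same):
        return "k"
    if any(shares_junction(r) for r, _ in same):
        return "j"
    if any(exon_overlap(r) for r, _ in same):
        return "o"
    if any(shares_junction(r) for r, _ in anti):
        return "s"
    if any(exon_overlap(r) for r, _ in anti):
        return "x"
    if any(exon_in_intron(r) for r, _ in ref_ts):
        return "i"
    genes = {id(g): g for _, g in ref_ts}
    if any(gene_in_intron(g) for g in genes.values()):
        return "y"
    return "u"


# ---------------------------------------------------------------------------
# splice events (direct per-strand branching, no coordinate reflection)


def brute_pairwise_events(t1: TranscriptModel, t2: TranscriptModel) -> set[tuple]:
    """Events as a set of (type, genomic coords) tuples."""
    assert t1.strand == t2.strand and t1.chrom == t2.chrom
    plus = t1.strand == "+"

    def tx(t):  # exons in transcription order as (start, end) genomic pairs
        ex = [(e.start, e.end) for e in t.exons]
        return ex if plus else ex[::-1]

    def donor(exon):  # genomic position of the exon's 3'-side boundary
        return exon[1] if plus else exon[0]

    def acceptor(exon):  # genomic position of the exon's 5'-side boundary
        return exon[0] if plus else exon[1]

    e1, e2 = tx(t1), tx(t2)
    gi1 = sorted(_junc(t1))
    gi2 = sorted(_junc(t2))
    events: set[tuple] = set()

    def overlaps(a, b):
        return a[0] < b[1] and b[0] < a[1]

    # SE / MXE via internal exons and genomic flanking introns
    def flanks(t, exon):  # genomic (left intron, right intron) of an internal exon
        ex = sorted((e.start, e.end) for e in t.exons)
        i = ex.index(exon)
        return (ex[i - 1][1], exon[0]), (exon[1], ex[i + 1][0])

    for a, b, other in ((t1, t2, gi2), (t2, t1, gi1)):
        ex = sorted((e.start, e.end) for e in a.exons)
        for exon in ex[1:-1]:
            (lA, lB), (rA, rB) = flanks(a, exon)
            if (lA, rB) in other:
                events.add(("SE", (lA, exon[0], exon[1], rB)))
    ex1 = sorted((e.start, e.end) for e in t1.exons)
    ex2 = sorted((e.start, e.end) for e in t2.exons)
    for m1 in ex1[1:-1]:
        for m2 in ex2[1:-1]:
            if overlaps(m1, m2):
                continue
            f1 = flanks(t1, m1)
            f2 = flanks(t2, m2)
            if f1[0][0] == f2[0][0] and f1[1][1] == f2[1][1]:
                lo, hi = sorted((m1, m2))
                events.add(("MXE", (f1[0][0], *lo, *hi, f1[1][1])))

    # A5E / A3E: overlapping exon pairs, boundary roles taken strand-aware
    def next_intron(t, exon):  # transcription-order next intron, genomic coords
        ex = tx(t)
        i = ex.index(exon)
        if i + 1 >= len(ex):
            return None
        nxt = ex[i + 1]
        return (exon[1], nxt[0]) if plus else (nxt[1], exon[0])

    def prev_intron(t, exon):
        ex = tx(t)
        i = ex.index(exon)
        if i == 0:
            return None
        prv = ex[i - 1]
        return (prv[1], exon[0]) if plus else (exon[1], prv[0])

    for x1 in e1:
        for x2 in e2:
            if not overlaps(x1, x2):
                continue
            n1, n2 = next_intron(t1, x1), next_intron(t2, x2)
            if (
                donor(x1) != donor(x2)
                and n1 is not None
                and n2 is not None
                and (n1[1] if plus else n1[0]) == (n2[1] if plus else n2[0])
            ):
                lo, hi = sorted((donor(x1), donor(x2)))
                far = n1[1] if plus else n1[0]
                events.add(("A5E", tuple(sorted((lo, hi, far)))))
            p1, p2 = prev_intron(t1, x1), prev_intron(t2, x2)
            if (
                acceptor(x1) != acceptor(x2)
                and p1 is not None
                and p2 is not None
                and (p1[0] if plus else p1[1]) == (p2[0] if plus else p2[1])
            ):
                lo, hi = sorted((acceptor(x1), acceptor(x2)))
                far = p1[0] if plus else p1[1]
                events.add(("A3E", tuple(sorted((lo, hi, far)))))

    # AFE / ALE on transcription-order terminal exons
    f1, f2 = e1[0], e2[0]
    n1, n2 = next_intron(t1, f1), next_intron(t2, f2)
    if (
        not overlaps(f1, f2)
        and n1 is not None
        and n2 is not None
        and (n1[1] if plus else n1[0]) == (n2[1] if plus else n2[0])
    ):
        lo, hi = sorted((f1, f2))
        far = n1[1] if plus else n1[0]
        events.add(("AFE", tuple(sorted((*lo, *hi, far)))))
    l1, l2 = e1[-1], e2[-1]
    p1, p2 = prev_intron(t1, l1), prev_intron(t2, l2)
    if (
        not overlaps(l1, l2)
        and p1 is not None
        and p2 is not None
        and (p1[0] if plus else p1[1]) == (p2[0] if plus else p2[1])
    ):
        lo, hi = sorted((l1, l2))
        far = p1[0] if plus else p1[1]
        events.add(("ALE", tuple(sorted((*lo, *hi, far)))))

    # IR
    for a, b in ((t1, t2), (t2, t1)):
        for s, e in _junc(a):
            if any(ex.start <= s and e <= ex.end for ex in b.exons):
                events.add(("IR", (s, e)))
    return events


# ---------------------------------------------------------------------------
# spliced coordinates


def brute_spliced_to_genomic(t: TranscriptModel) -> list[int]:
    """Genomic position of every spliced-coordinate base, 5'->3'."""
    positions = [p for e in t.exons for p in range(e.start, e.end)]
    return positions[::-1] if t.strand == "-" else positions


def brute_final_junction_position(t: TranscriptModel) -> int | None:
    """Spliced index of the junction between the last two exons: the first
    spliced coordinate of the 3'-terminal exon, found by walking bases."""
    if len(t.exons) < 2:
        return None
    g = brute_spliced_to_genomic(t)
    step = 1 if t.strand == "+" else -1
    breaks = [i + 1 for i in range(len(g) - 1) if g[i + 1] - g[i] != step]
    return breaks[-1]
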
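"""Coding / NMD / lncRNA classification of transcript models.

Open reading frames are called on the spliced transcript sequence (three
forward frames; the library consumes oriented cDNA models, so reverse
frames are not scanned).  Among the three longest ORFs the one with the
best (lowest) protein-homology E-value below the cutoff is representative;
without homology evidence the longest ORF is representative.

A transcript with a representative ORF is *NMD* (nonsense-mediated decay)
when it is spliced and the last base of its stop codon lies more than
50 nt upstream of the final splice junction in spliced coordinates —
the classic 50-bp rule for premature termination codons.  Otherwise it is
*protein_coding*.  A transcript with no qualifying ORF is *lncRNA* if its
spliced length exceeds 200 nt, else *short_noncoding*.  Mono-exonic
transcripts have no final junction and are never NMD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotation import AnnotationSet, GeneModel, TranscriptModel, fetch_seq, revcomp

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_START_CODONS = frozenset({"ATG"})
#: "alternative initiation codons" setting of common ORF finders
EXTENDED_START_CODONS = frozenset({"ATG", "CTG", "GTG", "TTG"})

NMD_DISTANCE_NT = 50
LNCRNA_MIN_LENGTH_NT = 200
DEFAULT_MIN_ORF_NT = 75
DEFAULT_EVALUE_CUTOFF = 1e-6

PROTEIN_CODING = "protein_coding"
NMD = "NMD"
LNCRNA = "lncRNA"
SHORT_NONCODING = "short_noncoding"


@dataclass(frozen=True)
class OpenReadingFrame:
    """An ORF in spliced transcript coordinates.

    ``[start, end)`` includes the stop codon; ``length`` is divisible by 3.
    ``homology_score`` is an optional E-value-like score (smaller = better).
    """

    start: int
    end: int
    frame: int
    homology_score: float | None = None

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0 or self.end <= self.start:
            raise ValueError(f"ORF length {self.end - self.start} not a positive multiple of 3")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BiotypeCall:
    biotype: str
    representative_orf: OpenReadingFrame | None = None

    def __post_init__(self) -> None:
        if self.biotype in (PROTEIN_CODING, NMD) and self.representative_orf is None:
            raise ValueError(f"{self.biotype} call requires a representative ORF")
        if self.biotype in (LNCRNA, SHORT_NONCODING) and self.representative_orf is not None:
            raise ValueError(f"{self.biotype} call must not carry an ORF")


def spliced_sequence(t: TranscriptModel, genome) -> str:
    """Exon sequences concatenated 5'->3' (reverse-complemented on '-')."""
    seq = "".join(fetch_seq(genome, t.chrom, e.start, e.end) for e in t.exons)
    return revcomp(seq) if t.strand == "-" else seq


def find_orfs(
    seq: str,
    start_codons: frozenset[str] = DEFAULT_START_CODONS,
    min_length: int = DEFAULT_MIN_ORF_NT,
) -> list[OpenReadingFrame]:
    """All maximal ORFs of length >= min_length in the three forward frames.

    Within each frame and stop-to-stop segment, the ORF runs from the first
    start codon to the stop codon (inclusive).  ORFs must terminate at a
    stop codon inside the sequence.
    """
    seq = seq.upper()
    orfs = []
    for frame in range(3):
        start_pos: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start_pos is None and codon in start_codons:
                start_pos = i
            elif codon in STOP_CODONS and start_pos is not None:
                end = i + 3
                if end - start_pos >= min_length:
                    orfs.append(OpenReadingFrame(start_pos, end, frame))
                start_pos = None
            elif codon in STOP_CODONS:
                start_pos = None
    orfs.sort(key=lambda o: (-o.length, o.start, o.frame))
    return orfs


def select_representative_orf(
    orfs: Sequence[OpenReadingFrame],
    homology_evalues: Mapping[int, float] | None = None,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> OpenReadingFrame | None:
    """Pick the representative among the three longest ORFs.

    ``homology_evalues`` maps ORF rank (1-based, by decreasing length) to
    the best protein E-value of that ORF.  The ORF with the lowest E-value
    at or below the cutoff wins; without qualifying hits, the longest ORF.
    """
    if not orfs:
        return None
    ranked = sorted(orfs, key=lambda o: (-o.length, o.start, o.frame))[:3]
    if homology_evalues:
        hits = [
            (homology_evalues[rank], rank, orf)
            for rank, orf in enumerate(ranked, start=1)
            if rank in homology_evalues and homology_evalues[rank] <= evalue_cutoff
        ]
        if hits:
            ev, rank, orf = min(hits, key=lambda h: (h[0], h[1]))
            return OpenReadingFrame(orf.start, orf.end, orf.frame, homology_score=ev)
    return ranked[0]


def final_junction_spliced_position(t: TranscriptModel) -> int | None:
    """Spliced coordinate of the junction between the last two exons.

    In transcription order: the cumulative length of all exons but the
    3'-terminal one.  None for mono-exonic transcripts.
    """
    if not t.is_spliced:
        return None
    lengths = [len(e) for e in t.exons]
    if t.strand == "-":
        lengths = lengths[::-1]
    return sum(lengths[:-1])


def classify_biotype(
    t: TranscriptModel,
    genome,
    start_codons: frozenset[str] = DEFAULT_START_CODONS,
    min_orf_length: int = DEFAULT_MIN_ORF_NT,
    homology_evalues: Mapping[int, float] | None = None,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> BiotypeCall:
    """Biotype of one transcript: protein_coding, NMD, lncRNA or short_noncoding."""
    seq = spliced_sequence(t, genome)
    orfs = find_orfs(seq, start_codons, min_orf_length)
    rep = select_representative_orf(orfs, homology_evalues, evalue_cutoff)
    if rep is None:
        if len(seq) > LNCRNA_MIN_LENGTH_NT:
            return BiotypeCall(LNCRNA)
        return BiotypeCall(SHORT_NONCODING)
    junction = final_junction_spliced_position(t)
    if junction is not None:
        # distance from the last base of the stop codon to the final junction
        distance = junction - rep.end
        if distance > NMD_DISTANCE_NT:
            return BiotypeCall(NMD, rep)
    return BiotypeCall(PROTEIN_CODING, rep)


def gene_biotype(calls: Iterable[BiotypeCall]) -> str:
    """Gene label: protein_coding if any member codes, else lncRNA, else other."""
    biotypes = {c.biotype for c in calls}
    if PROTEIN_CODING in biotypes:
        return PROTEIN_CODING
    if LNCRNA in biotypes:
        return LNCRNA
    return "other"


def load_homology_tsv(path) -> dict[str, dict[int, float]]:
    """Optional protein-homology evidence: TSV (transcript_id, orf_rank, evalue)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[int, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.transcript_id), {})[int(row.orf_rank)] = float(row.evalue)
    return out


def classify_catalogue_biotypes(
    catalogue: AnnotationSet,
    genome,
    homology: Mapping[str, Mapping[int, float]] | None = None,
    start_codons: frozenset[str] = DEFAULT_START_CODONS,
    min_orf_length: int = DEFAULT_MIN_ORF_NT,
) -> dict[str, BiotypeCall]:
    calls = {}
    for t in catalogue.transcripts():
        ev = homology.get(t.transcript_id) if homology else None
        calls[t.transcript_id] = classify_biotype(
            t, genome, start_codons, min_orf_length, ev
        )
    return calls
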
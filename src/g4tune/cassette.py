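"""Expression-cassette chassis modelling and strand-aware motif insertion.

The chassis is a standardized core-promoter + 5'UTR control unit ("BPCU"):
a 41-bp human CMV-IE1 core promoter fused to a 57-nt 5'UTR, 98 bp in total.
Coordinates are TSS-relative with no position 0: +1 is the first UTR
nucleotide (the transcription start), -1 the last core-promoter nucleotide.
Insertion at coordinate p places a motif immediately 3' of nucleotide p, so
the two default optima sit directly upstream of the TSS (-1, DNA level) and
6 nt into the UTR (+6, RNA level).

Strand semantics: DNA-level motifs act on the template strand, so their
G-rich sequence is inserted into the coding strand as its reverse
complement; RNA-level motifs form in the transcript, so their sequence is
inserted verbatim (U rendered as T).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

from .motifs import G4Motif, Level

#: The canonical minimal human CMV-IE1 core promoter region (TATA box
#: through the +1 area), 41 bp, as packaged in common expression vectors.
DEFAULT_CORE_PROMOTER = "AGGTCTATATAAGCAGAGCTCGTTTAGTGAACCGTCAGATC"

#: SYNTHETIC placeholder 5'UTR, 57 nt.  The authentic bioproduction UTR the
#: chassis was built around is proprietary and is NOT shipped; this
#: stand-in is guanine-free (so it can neither form quadruplexes nor
#: contribute upstream AUGs) and is intended only to make the default
#: chassis runnable.  Supply the licensed sequence via ``assemble_bpcu``.
DEFAULT_UTR_PLACEHOLDER = (
    "CCTACACTCTTCCTTCACACCATCCTCTTCACTACTCCAACACCTCTTCAATCCACC"
)

#: Minimal SYNTHETIC reporter CDS used in examples and tests (not a real
#: gene): start codon, ten codons, stop.
DEFAULT_REPORTER_CDS = "ATGGCTAGCAAAGCTGCTGCTAGCAAAGCTGCTTAA"

_DNA_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{what} must be a nonempty DNA sequence")
    bad = set(seq) - _DNA_BASES
    if bad:
        raise ValueError(f"{what} contains non-DNA characters {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class BPCU:
    """Core promoter + 5'UTR control unit (coding strand).

    ``tss_index`` is the 0-based index of the +1 nucleotide in the fused
    sequence, i.e. ``len(core_promoter)``.
    """

    core_promoter: str
    utr: str

    @property
    def tss_index(self) -> int:
        return len(self.core_promoter)

    @property
    def sequence(self) -> str:
        return self.core_promoter + self.utr

    def __len__(self) -> int:
        return len(self.core_promoter) + len(self.utr)


def assemble_bpcu(core_promoter: Optional[str] = None, utr: Optional[str] = None) -> BPCU:
    """Fuse a core promoter and a 5'UTR into a BPCU.

    Defaults give the packaged 41 + 57 = 98 bp unit (with the placeholder
    UTR — see :data:`DEFAULT_UTR_PLACEHOLDER`).
    """
    if core_promoter is None:
        core_promoter = DEFAULT_CORE_PROMOTER
    if utr is None:
        utr = DEFAULT_UTR_PLACEHOLDER
    return BPCU(_check_dna(core_promoter, "core promoter"), _check_dna(utr, "5'UTR"))


@dataclass(frozen=True)
class InsertionSite:
    """TSS-relative insertion coordinate (no position 0).

    DNA-level sites are negative (within the core promoter); RNA-level
    sites are positive (within the UTR).
    """

    level: Level
    position: int

    def __post_init__(self):
        object.__setattr__(self, "level", Level(self.level))
        if self.position == 0:
            raise ValueError("TSS-relative coordinates have no position 0")
        if self.level is Level.DNA and self.position > 0:
            raise ValueError(
                f"DNA-level sites must be upstream of the TSS (negative), got +{self.position}"
            )
        if self.level is Level.RNA and self.position < 0:
            raise ValueError(
                f"RNA-level sites must be within the UTR (positive), got {self.position}"
            )


#: Default optima identified for the packaged chassis.
DEFAULT_DNA_SITE = InsertionSite(Level.DNA, -1)
DEFAULT_RNA_SITE = InsertionSite(Level.RNA, 6)

#: Default candidate panel: 7 DNA sites spanning the 41-bp core promoter and
#: 6 RNA sites spanning the 57-nt UTR.  Only -1 and +6 are chassis-validated
#: optima; the remaining coordinates are an editable screening grid.
DEFAULT_SITE_PANEL = (
    [InsertionSite(Level.DNA, p) for p in (-37, -31, -25, -19, -13, -7, -1)]
    + [InsertionSite(Level.RNA, p) for p in (6, 14, 22, 30, 38, 46)]
)


def candidate_sites(config: Optional[Sequence] = None) -> List[InsertionSite]:
    """Insertion-site panel.

    ``None`` returns the default 13-site screening panel; an empty config
    returns only the two validated optima (-1, +6); otherwise each entry is
    an ``InsertionSite`` or a ``(level, position)`` pair (validated).
    """
    if config is None:
        return list(DEFAULT_SITE_PANEL)
    sites = []
    for entry in config:
        if isinstance(entry, InsertionSite):
            sites.append(entry)
        else:
            level, position = entry
            sites.append(InsertionSite(level, int(position)))
    if not sites:
        return [DEFAULT_DNA_SITE, DEFAULT_RNA_SITE]
    return sites


@dataclass(frozen=True)
class Insertion:
    """One placed motif: site, motif id, and the coding-strand sequence."""

    site: InsertionSite
    motif_id: str
    coding_strand_seq: str


@dataclass(frozen=True)
class ExpressionCassette:
    """A full cassette: optional proximal promoter, BPCU with insertions,
    CDS, optional 3'UTR.

    ``assembled`` is the coding-strand sequence; ``segment_map`` lists
    ``(name, start, end)`` provenance intervals (0-based half-open) that
    tile it exactly.
    """

    bpcu: BPCU
    cds: str = ""
    proximal_promoter: str = ""
    utr3: str = ""
    insertions: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "insertions", tuple(self.insertions))
        seen = set()
        for ins in self.insertions:
            key = (ins.site.level, ins.site.position)
            if key in seen:
                raise ValueError(f"duplicate insertion at site {key}")
            seen.add(key)

    # -- coordinate mapping ------------------------------------------------
    def _core_index(self, position: int) -> int:
        """Insertion index within the core promoter for a negative coord."""
        idx = self.bpcu.tss_index + position + 1
        if not 1 <= idx <= self.bpcu.tss_index:
            raise ValueError(
                f"DNA coordinate {position} outside the core promoter "
                f"(-{self.bpcu.tss_index}..-1)"
            )
        return idx

    def _utr_index(self, position: int) -> int:
        """Insertion index within the UTR for a positive coord."""
        if not 1 <= position <= len(self.bpcu.utr):
            raise ValueError(
                f"RNA coordinate +{position} outside the UTR (+1..+{len(self.bpcu.utr)})"
            )
        return position

    def _engineered_parts(self):
        """Split promoter and UTR around their insertions.

        Returns two lists of (segment_name, sequence) tuples.
        """
        dna = sorted(
            (i for i in self.insertions if i.site.level is Level.DNA),
            key=lambda i: i.site.position,
        )
        rna = sorted(
            (i for i in self.insertions if i.site.level is Level.RNA),
            key=lambda i: i.site.position,
        )
        core = self.bpcu.core_promoter
        promoter_parts, pos = [], 0
        for ins in dna:
            cut = self._core_index(ins.site.position)
            promoter_parts.append(("core_promoter", core[pos:cut]))
            promoter_parts.append((f"insertion:{ins.motif_id}", ins.coding_strand_seq))
            pos = cut
        promoter_parts.append(("core_promoter", core[pos:]))
        utr = self.bpcu.utr
        utr_parts, pos = [], 0
        for ins in rna:
            cut = self._utr_index(ins.site.position)
            utr_parts.append(("utr5", utr[pos:cut]))
            utr_parts.append((f"insertion:{ins.motif_id}", ins.coding_strand_seq))
            pos = cut
        utr_parts.append(("utr5", utr[pos:]))
        return promoter_parts, utr_parts

    @property
    def segments(self) -> List[Tuple[str, str]]:
        promoter_parts, utr_parts = self._engineered_parts()
        parts = []
        if self.proximal_promoter:
            parts.append(("proximal_promoter", self.proximal_promoter))
        parts.extend(promoter_parts)
        parts.extend(utr_parts)
        if self.cds:
            parts.append(("cds", self.cds))
        if self.utr3:
            parts.append(("utr3", self.utr3))
        return [(name, seq) for name, seq in parts if seq]

    @property
    def assembled(self) -> str:
        return "".join(seq for _, seq in self.segments)

    @property
    def segment_map(self) -> List[Tuple[str, int, int]]:
        out, pos = [], 0
        for name, seq in self.segments:
            out.append((name, pos, pos + len(seq)))
            pos += len(seq)
        return out

    @property
    def engineered_utr(self) -> str:
        _, utr_parts = self._engineered_parts()
        return "".join(seq for _, seq in utr_parts)


def new_cassette(
    bpcu: Optional[BPCU] = None,
    cds: str = DEFAULT_REPORTER_CDS,
    proximal_promoter: str = "",
    utr3: str = "",
) -> ExpressionCassette:
    """Convenience constructor for an unengineered cassette."""
    return ExpressionCassette(
        bpcu=bpcu or assemble_bpcu(),
        cds=_check_dna(cds, "CDS") if cds else "",
        proximal_promoter=_check_dna(proximal_promoter, "proximal promoter")
        if proximal_promoter
        else "",
        utr3=_check_dna(utr3, "3'UTR") if utr3 else "",
    )


def insert_motif(
    cassette: ExpressionCassette, motif: G4Motif, site: InsertionSite
) -> ExpressionCassette:
    """Insert ``motif`` at ``site``, returning a new cassette.

    DNA-level motifs go onto the template strand, so the coding strand gains
    the reverse complement of the motif; RNA-level motifs are inserted
    verbatim (U -> T).  The original flanks are untouched and insertion is
    reversible via :func:`remove_insertion`.
    """
    if motif.spec.level is not site.level:
        raise ValueError(
            f"{motif.spec.level.value}-level motif cannot occupy a "
            f"{site.level.value}-level site"
        )
    # validate the coordinate against this chassis before committing
    if site.level is Level.DNA:
        cassette._core_index(site.position)
        coding = reverse_complement(motif.sequence)
    else:
        cassette._utr_index(site.position)
        coding = motif.sequence.replace("U", "T")
    motif_id = motif.label or f"{motif.spec.level.value}@{site.position:+d}"
    ins = Insertion(site=site, motif_id=motif_id, coding_strand_seq=coding)
    return replace(cassette, insertions=cassette.insertions + (ins,))


def remove_insertion(cassette: ExpressionCassette, motif_id: str) -> ExpressionCassette:
    """Remove the named insertion (round-trips the assembled sequence)."""
    kept = tuple(i for i in cassette.insertions if i.motif_id != motif_id)
    if len(kept) == len(cassette.insertions):
        raise ValueError(f"no insertion named {motif_id!r}")
    return replace(cassette, insertions=kept)


def extract_template_motif(cassette: ExpressionCassette, motif_id: str) -> str:
    """Template-strand sequence of a DNA-level insertion (the original motif)."""
    for ins in cassette.insertions:
        if ins.motif_id == motif_id:
            if ins.site.level is not Level.DNA:
                raise ValueError(f"{motif_id!r} is not a DNA-level insertion")
            return reverse_complement(ins.coding_strand_seq)
    raise ValueError(f"no insertion named {motif_id!r}")


def transcript_of(cassette: ExpressionCassette) -> str:
    """The transcript (RNA alphabet): engineered 5'UTR + CDS.

    Promoter-region (DNA-level) insertions lie upstream of the TSS and are
    not transcribed.
    """
    if not cassette.cds:
        raise ValueError("cassette has no CDS")
    return (cassette.engineered_utr + cassette.cds).replace("T", "U")


def cds_offset_of(cassette: ExpressionCassette) -> int:
    """0-based position of the intended start codon within the transcript."""
    return len(cassette.engineered_utr)


def scan_upstream_starts(transcript: str, cds_offset: int) -> List[int]:
    """0-based positions of every AUG starting strictly upstream of the CDS."""
    rna = transcript.upper().replace("T", "U")
    return [i for i in range(min(cds_offset, len(rna) - 2)) if rna[i:i + 3] == "AUG"]


def introduces_upstream_start(
    motif: G4Motif,
    bpcu: Optional[BPCU] = None,
    site: InsertionSite = DEFAULT_RNA_SITE,
    cds: str = DEFAULT_REPORTER_CDS,
) -> bool:
    """Does inserting this RNA-level motif create an upstream AUG?

    Builds the cassette, takes its transcript, and compares the upstream-AUG
    count against the unengineered transcript.
    """
    base = new_cassette(bpcu=bpcu, cds=cds)
    engineered = insert_motif(base, motif, site)
    before = scan_upstream_starts(transcript_of(base), cds_offset_of(base))
    after = scan_upstream_starts(transcript_of(engineered), cds_offset_of(engineered))
    return len(after) > len(before)
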
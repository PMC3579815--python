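"""Transcript models: exon/intron structure and coordinate conversions.

A :class:`TranscriptModel` describes a single transcript of a gene in
*gene-local* coordinates (0-based, half-open, 5'->3'; no genomic strand
logic).  cDNA coordinates throughout the package are CDS-relative HGVS
``c.`` positions: ``c.1`` is the A of the start codon.  Intronic positions
are expressed as ``(anchor, offset)`` pairs, e.g. ``c.441+2`` is anchor 441,
offset +2.

The model may or may not carry the underlying gene sequence.  Coordinate
arithmetic (exon membership, codon numbering, frame bookkeeping) works
without a sequence, which is how the bundled BRCA1/BRCA2 exon maps are
used; sequence-level operations (mature mRNA assembly, translation)
require it.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TranscriptModel:
    """Exon structure of one transcript.

    Parameters
    ----------
    gene_id
        Identifier echoed into outputs.
    exons
        Ordered, non-overlapping, strictly increasing gene-local spans
        (0-based half-open).
    sequence
        Optional gene-local reference sequence covering every exon.
    cds_offset
        Number of mature-mRNA bases 5' of ``c.1`` (default 0: the mature
        mRNA starts at the start codon, as in the synthetic genes).
    cds_len
        CDS length in nucleotides, stop codon included.  Defaults to the
        mature mRNA length minus ``cds_offset``.
    """

    gene_id: str
    exons: list[tuple[int, int]]
    sequence: str | None = None
    cds_offset: int = 0
    cds_len: int | None = None
    _cum: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("transcript must have at least one exon")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"empty or inverted exon span ({start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"exons overlap or are out of order near gene-local {start}"
                )
            prev_end = end
        if self.sequence is not None and self.exons[-1][1] > len(self.sequence):
            raise ValueError("exon span extends beyond the supplied sequence")
        cum = [0]
        for start, end in self.exons:
            cum.append(cum[-1] + (end - start))
        self._cum = cum
        if self.cds_len is None:
            self.cds_len = self.mrna_len - self.cds_offset
        if self.cds_len + self.cds_offset > self.mrna_len:
            raise ValueError("CDS extends beyond the mature mRNA")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def mrna_len(self) -> int:
        return self._cum[-1]

    def exon_lengths(self) -> list[int]:
        return [end - start for start, end in self.exons]

    def exon_cdna_bounds(self) -> list[tuple[int, int]]:
        """Per-exon (first, last) cDNA position, 1-based inclusive."""
        return [
            (self._cum[i] + 1 - self.cds_offset, self._cum[i + 1] - self.cds_offset)
            for i in range(self.n_exons)
        ]

    def exon_containing(self, cdna_pos: int) -> int:
        """0-based index of the exon holding a cDNA position."""
        for i, (lo, hi) in enumerate(self.exon_cdna_bounds()):
            if lo <= cdna_pos <= hi:
                return i
        raise ValueError(
            f"cDNA position {cdna_pos} outside transcript {self.gene_id} "
            f"(1..{self.mrna_len - self.cds_offset})"
        )

    def donor_junctions(self) -> list[int]:
        """Gene-local junction per intron: index of the first intronic base."""
        return [end for _, end in self.exons[:-1]]

    def acceptor_junctions(self) -> list[int]:
        """Gene-local junction per intron: index of the first exonic base."""
        return [start for start, _ in self.exons[1:]]

    # -- coordinate conversion --------------------------------------------

    def cdna_to_gene_local(self, cdna_pos: int, offset: int = 0) -> int:
        """Map ``(c.anchor, intron offset)`` to a gene-local index."""
        i = self.exon_containing(cdna_pos)
        lo, _ = self.exon_cdna_bounds()[i]
        g = self.exons[i][0] + (cdna_pos - lo)
        if offset:
            g += offset
            start, end = self.exons[i]
            if start <= g < end:
                raise ValueError(
                    f"offset {offset:+d} from c.{cdna_pos} lands inside an exon"
                )
        return g

    def gene_local_to_cdna(self, g: int) -> tuple[int, int]:
        """Map a gene-local index to ``(c.anchor, intron offset)``.

        Exonic bases return offset 0.  Intronic bases anchor to the nearer
        flanking exon edge (donor side positive, acceptor side negative),
        matching HGVS convention.
        """
        bounds = self.exon_cdna_bounds()
        for i, (start, end) in enumerate(self.exons):
            if start <= g < end:
                return bounds[i][0] + (g - start), 0
        for i in range(self.n_exons - 1):
            intron_start = self.exons[i][1]
            intron_end = self.exons[i + 1][0]
            if intron_start <= g < intron_end:
                d_donor = g - intron_start + 1
                d_acceptor = intron_end - g
                if d_donor <= d_acceptor:
                    return bounds[i][1], d_donor
                return bounds[i + 1][0], -d_acceptor
        raise ValueError(f"gene-local position {g} outside transcript {self.gene_id}")

    # -- sequence-level views ---------------------------------------------

    def _require_sequence(self) -> str:
        if self.sequence is None:
            raise ValueError(
                f"transcript {self.gene_id} carries no sequence; "
                "sequence-level operation unavailable"
            )
        return self.sequence

    def mature_mrna(self) -> str:
        seq = self._require_sequence()
        return "".join(seq[start:end] for start, end in self.exons)

    def cds_sequence(self) -> str:
        mrna = self.mature_mrna()
        return mrna[self.cds_offset : self.cds_offset + self.cds_len]

    def intron_sequence(self, intron_index: int) -> str:
        seq = self._require_sequence()
        return seq[self.exons[intron_index][1] : self.exons[intron_index + 1][0]]

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_cdna_exon_ends(
        cls,
        gene_id: str,
        exon_ends: list[int],
        intron_len: int = 200,
    ) -> "TranscriptModel":
        """Build a sequence-free model from cumulative cDNA exon ends.

        ``exon_ends[i]`` is the cDNA (c.) position of the last base of exon
        ``i``.  Introns are given a uniform placeholder length, large enough
        for splice-region offset arithmetic; no sequence is attached.
        """
        exons: list[tuple[int, int]] = []
        g = 0
        prev = 0
        for end in exon_ends:
            if end <= prev:
                raise ValueError("exon ends must be strictly increasing")
            length = end - prev
            exons.append((g, g + length))
            g += length + intron_len
            prev = end
        return cls(gene_id=gene_id, exons=exons, sequence=None)
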
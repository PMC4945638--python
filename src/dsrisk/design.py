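"""dsRNA synthesis-template extraction and T7-tailed primer construction.

In vitro transcription of dsRNA uses a PCR product whose primers carry a
5' T7 RNA polymerase promoter tail; the gene-specific 3' part anchors the
primer in the template.
"""

from __future__ import annotations

import dataclasses

from .io import ALPHABET, SequenceRecord

#: T7 RNA polymerase promoter tail prepended to every dsRNA synthesis primer
T7_PROMOTER = "TAATACGACTCACTATAGGGAGA"
assert len(T7_PROMOTER) == 23

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass(frozen=True)
class DsRnaTemplate:
    source_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("template sequence inconsistent with coordinates")


@dataclasses.dataclass(frozen=True)
class T7Primer:
    gene_specific: str
    orientation: str  # forward | reverse

    def __post_init__(self) -> None:
        if not self.gene_specific:
            raise ValueError("gene-specific primer part is empty")
        bad = set(self.gene_specific) - ALPHABET
        if bad:
            raise ValueError(f"invalid characters in primer: {sorted(bad)}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")

    @property
    def full(self) -> str:
        return T7_PROMOTER + self.gene_specific


def extract_template(
    seq: SequenceRecord, start: int, end: int
) -> DsRnaTemplate:
    """Cut the dsRNA synthesis template out of a source sequence
    (1-based inclusive coordinates)."""
    if not (1 <= start <= end <= len(seq.residues)):
        raise ValueError(
            f"region {start}..{end} out of range for {seq.id!r} of length {len(seq.residues)}"
        )
    return DsRnaTemplate(seq.id, start, end, seq.residues[start - 1 : end])


def make_t7_primer(gene_specific: str, orientation: str) -> T7Primer:
    """Build a full synthesis primer: T7 promoter + gene-specific part."""
    return T7Primer(gene_specific.upper().replace("U", "T"), orientation)


def _find_once(template: str, probe: str, primer_name: str) -> int:
    first = template.find(probe)
    if first == -1:
        raise ValueError(f"no binding site for {primer_name} primer in template")
    if template.find(probe, first + 1) != -1:
        raise ValueError(f"ambiguous binding: {primer_name} primer matches template more than once")
    return first


def predict_amplicon(
    template: SequenceRecord, fwd: T7Primer, rev: T7Primer
) -> dict:
    """Predicted PCR product of a T7-tailed primer pair on a template.

    The forward gene-specific part must occur exactly once on the given
    strand and the reverse part exactly once as reverse-complement. Returns
    the genomic span (template nt covered) and the full synthesised product
    length including both promoter tails.
    """
    f0 = _find_once(template.residues, fwd.gene_specific, "forward")
    rc = reverse_complement(rev.gene_specific)
    r0 = _find_once(template.residues, rc, "reverse")
    start = f0 + 1
    end = r0 + len(rc)
    if end <= f0:
        raise ValueError("reverse primer binds upstream of forward primer")
    span = end - start + 1
    return {
        "start": start,
        "end": end,
        "genomic_span": span,
        "full_length": span + 2 * len(T7_PROMOTER),
    }


def cdna_length(utr5: int, orf: int, utr3: int) -> int:
    """Total cDNA length from its 5'UTR, ORF (stop codon included) and 3'UTR
    segment lengths."""
    for name, v in (("utr5", utr5), ("orf", orf), ("utr3", utr3)):
        if v < 0:
            raise ValueError(f"{name} length must be non-negative")
    return utr5 + orf + utr3


def protein_length(orf_nt: int) -> int:
    """Encoded protein length (aa) of an ORF that includes its stop codon."""
    if orf_nt < 6 or orf_nt % 3:
        raise ValueError("ORF length must be a positive multiple of 3 (incl. stop)")
    return orf_nt // 3 - 1


# The six published dsRNA synthesis primers (gene-specific parts); used to
# validate the promoter constant and exercised by the tests.
DSRNA_PRIMERS = {
    ("dsSC", "forward"): "ACACTATTTCCATGTGTTCAG",
    ("dsSC", "reverse"): "GCATCTCAGCCAATCG",
    ("dsDVV", "forward"): "GCTCTTTTCCCATGTGTAC",
    ("dsDVV", "reverse"): "GCATTTCAGCCAAACG",
    ("dsGUS", "forward"): "GGGCGAACAGTTCCTGATTA",
    ("dsGUS", "reverse"): "GGCACAGCACATCAAAGAGA",
}

for (_name, _ori), _gs in DSRNA_PRIMERS.items():
    assert make_t7_primer(_gs, _ori).full.startswith(T7_PROMOTER)
del _name, _ori, _gs
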
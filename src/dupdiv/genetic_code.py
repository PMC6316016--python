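"""Standard genetic code constants (built from Biopython's table 1)."""

from Bio.Data.CodonTable import standard_dna_table

CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

BASES = "ACGT"


def is_sense(codon: str) -> bool:
    return codon in CODON_TO_AA
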
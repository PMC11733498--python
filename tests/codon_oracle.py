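"""Independent genetic-code oracle for degeneracy tests.

The standard code is hard-coded here (not taken from any library the
implementation uses) so the test has a genuinely independent reference.
"""

ORACLE_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_classify(codon: str, pos: int, code=ORACLE_CODE) -> str:
    """Brute-force degeneracy: substitute all three other bases."""
    aa = code[codon]
    n_change = sum(
        1
        for b in "ACGT"
        if b != codon[pos] and code[codon[:pos] + b + codon[pos + 1:]] != aa
    )
    if n_change == 3:
        return "zerofold"
    if n_change == 0:
        return "fourfold"
    return "other"
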
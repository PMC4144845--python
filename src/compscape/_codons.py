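"""Codon bookkeeping shared by the mutation generator and the NS statistics."""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"

_table = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid, with '*' for the three stop codons
CODON_AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_AA[_stop] = "*"

SENSE_CODONS = sorted(c for c, aa in CODON_AA.items() if aa != "*")


def random_orf(n_codons: int, rng: np.random.Generator) -> str:
    """Random ORF of ``n_codons`` sense codons (no stop codons anywhere)."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def snp_effect(orf: str, pos0: int, alt: str) -> str:
    """Coding effect of substituting ``alt`` at 0-based ORF position ``pos0``.

    Returns ``synonymous``, ``nonsynonymous`` or ``nonsense`` (stop gain).
    """
    cs = (pos0 // 3) * 3
    codon = orf[cs : cs + 3]
    within = pos0 - cs
    mutated = codon[:within] + alt + codon[within + 1 :]
    aa0, aa1 = CODON_AA[codon], CODON_AA[mutated]
    if aa1 == aa0:
        return "synonymous"
    if aa1 == "*":
        return "nonsense"
    return "nonsynonymous"
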
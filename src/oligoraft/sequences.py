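"""Reference protein sequences and oligomer compositions.

Two amyloidogenic monomers are modelled: human amylin (islet amyloid
polypeptide, 37 residues) and a 130-residue tau construct — the four-repeat
microtubule-binding fragment (K18, tau 244-372 of the 2N4R numbering) with
an initiator methionine. The fragment's hydrophobic landmarks (V6, I35,
I66, I86, I112, V121 in construct numbering) sit exactly at the K18 repeat
positions, and amylin's at C7, L16, I26, V32.

Oligomers are named by composition: ``1am``..``4am`` homo-amylin,
``1tau``..``4tau`` homo-tau, ``1tam`` the tau-amylin hetero-dimer (one of
each) and ``2tam`` the hetero-tetramer (two of each, chain order
amylin-tau-tau-amylin).
"""

from __future__ import annotations

__all__ = [
    "AMYLIN_SEQUENCE",
    "TAU_SEQUENCE",
    "OLIGOMERS",
    "oligomer_chains",
    "oligomer_residue_count",
]

AMYLIN_SEQUENCE = "KCNTATCATQRLANFLVHSSNNFGAILSSTNVGSNTY"

TAU_SEQUENCE = (
    "M"
    "QTAPVPMPDLKNVKSKIGSTENLKHQPGGG"
    "KVQIINKKLDLSNVQSKCGSKDNIKHVPGG"
    "GSVQIVYKPVDLSKVTSKCGSLGNIHHKPG"
    "GGQVEVKSEKLDFKDRVQSKIGSLDNITHV"
    "PGGGNKKIE"
)

assert len(AMYLIN_SEQUENCE) == 37
assert len(TAU_SEQUENCE) == 130

#: oligomer name -> ordered monomer types of its chains
OLIGOMERS: dict[str, tuple[str, ...]] = {
    "1am": ("amylin",),
    "2am": ("amylin", "amylin"),
    "4am": ("amylin",) * 4,
    "1tau": ("tau",),
    "2tau": ("tau", "tau"),
    "4tau": ("tau",) * 4,
    "1tam": ("tau", "amylin"),
    "2tam": ("amylin", "tau", "tau", "amylin"),
}

_SEQ = {"amylin": AMYLIN_SEQUENCE, "tau": TAU_SEQUENCE}


def oligomer_chains(name: str) -> list[tuple[str, str, str]]:
    """Chains of an oligomer as (chain_id, monomer_type, sequence)."""
    try:
        monomers = OLIGOMERS[name]
    except KeyError:
        raise KeyError(f"unknown oligomer {name!r}; known: {sorted(OLIGOMERS)}") from None
    return [(chr(ord("A") + i), m, _SEQ[m]) for i, m in enumerate(monomers)]


def oligomer_residue_count(name: str) -> int:
    """Total amino-acid count of an oligomer (e.g. 167 for the hetero-dimer)."""
    return sum(len(seq) for _, _, seq in oligomer_chains(name))
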
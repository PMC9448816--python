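"""Nearest-neighbor melting temperatures for guide features.

The guide spacer hybridizes to its complementary DNA strand as an RNA:DNA
heteroduplex; its melting temperature is computed from the packaged Sugimoto
RNA/DNA nearest-neighbor ΔH/ΔS parameters.  Legacy segment temperatures
(30-mer context and three spacer subsegments) use a DNA/DNA parameter set,
mirroring earlier sequence-only scoring schemes.

Conditions are fixed package-wide so the features are deterministic:
50 mM Na+, 25 nM per strand, Schildkraut-Lifson salt correction.
"""

from __future__ import annotations

from Bio.SeqUtils import MeltingTemp as mt

#: fixed solution conditions (mM for Na, nM for strand concentrations)
TM_CONDITIONS = {"Na": 50.0, "dnac1": 25.0, "dnac2": 25.0, "saltcorr": 1}


def heteroduplex_tm(spacer: str, check_length: bool = True) -> float:
    """Tm (°C) of the RNA spacer hybridized to its complementary DNA strand.

    ``spacer`` is the spacer sequence in DNA letters (T for U); it is
    interpreted as the RNA strand of the hybrid.
    """
    spacer = spacer.upper()
    if check_length and len(spacer) != 20:
        raise ValueError(f"spacer must be 20 nt, got {len(spacer)}")
    if not spacer:
        raise ValueError("empty sequence")
    return float(mt.Tm_NN(spacer, nn_table=mt.R_DNA_NN1, **TM_CONDITIONS))


def dna_duplex_tm(seq: str) -> float:
    """Tm (°C) of a DNA duplex (SantaLucia 2004 parameters)."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    return float(mt.Tm_NN(seq, nn_table=mt.DNA_NN3, **TM_CONDITIONS))


def segment_tms(context_30: str) -> dict[str, float]:
    """Legacy Tm block: full 30-mer + spacer subsegments 16-20, 8-15, 3-7.

    Spacer positions are 1-based (spacer = context positions 5..24).
    """
    context_30 = context_30.upper()
    if len(context_30) != 30:
        raise ValueError(f"context must be 30 nt, got {len(context_30)}")
    spacer = context_30[4:24]
    return {
        "context_30": dna_duplex_tm(context_30),
        "spacer_16_20": dna_duplex_tm(spacer[15:20]),
        "spacer_8_15": dna_duplex_tm(spacer[7:15]),
        "spacer_3_7": dna_duplex_tm(spacer[2:7]),
    }
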
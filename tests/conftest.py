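"""Shared fixtures: deterministic prototype proteins and called systems.

The prototype sequences are synthetic stand-ins modelled on the canonical
spanins (lambda Rz/Rz1, T4 PseT.3/PseT.2, T1 gp11): hand-written strings
with the same signal anatomy, lengths and cysteine placements, so every
expected number in the tests is fixed by construction.
"""

from __future__ import annotations

import pytest

from spaninscan.caller import SpaninComponent, SpaninSystem
from spaninscan.genome_io import OrfCandidate
from spaninscan.topology import classify_topology, periplasmic_domain

_HYDRO21 = "LLVVAILLVVAILLVVAILLV"  # 21-residue TMD block


def _tail(n: int, cys_at: tuple[int, ...] = ()) -> str:
    base = ("NDEQSTGKAR" * 40)[:n]
    chars = list(base)
    for p in cys_at:
        chars[p] = "C"
    return "".join(chars)


# lambda-like pair: i-spanin 153 aa with two periplasmic Cys, o-spanin 60 aa
# (lipoylated Cys at residue 21, one Cys in its mature 39-aa domain)
LAMBDA_I = "MKRT" + _HYDRO21 + _tail(128, cys_at=(70, 120))
LAMBDA_O = "MRNQST" + "LLVVALLVVAL" + "LSGC" + _tail(39, cys_at=(8,))

# T4-like pair: i-spanin 117 aa without Cys, o-spanin 83 aa with two Cys
T4_I = "MKRT" + _HYDRO21 + _tail(92)
T4_O = "MRNQ" + "LLVVALLVVAL" + "LSGC" + _tail(64, cys_at=(46, 57))

# T1-gp11-like u-spanin: lipoprotein signal, Cys-free periplasmic domain,
# C-terminal TMD
GP11_U = "MRNQ" + "LLVVALLVVAL" + "LSGC" + _tail(70) + _HYDRO21

# soluble decoy protein (no membrane signal at all)
SOLUBLE = "M" + _tail(110)


def make_component(role: str, protein: str, start: int = 0, strand: str = "+") -> SpaninComponent:
    """Wrap a protein into a called component at an arbitrary genome position."""
    call = classify_topology(protein)
    _, peri = periplasmic_domain(call, protein)
    orf = OrfCandidate(
        start=start,
        end=start + 3 * len(protein),
        strand=strand,
        frame=0,
        aa_seq=protein,
        start_codon="ATG",
    )
    return SpaninComponent(role=role, orf=orf, topology=call, periplasmic_seq=peri)


@pytest.fixture(scope="session")
def lambda_like_system() -> SpaninSystem:
    i = make_component("i", LAMBDA_I, start=100)
    o = make_component("o", LAMBDA_O, start=300)
    return SpaninSystem(i=i, o=o, architecture="embedded", overlap_bp=183,
                       frame_offset="+1", rel_start_frac=0.44, rel_end_frac=0.96)


@pytest.fixture(scope="session")
def t4_like_system() -> SpaninSystem:
    i = make_component("i", T4_I, start=100)
    o = make_component("o", T4_O, start=1100)
    return SpaninSystem(i=i, o=o, architecture="separated", gap_bp=649)


@pytest.fixture(scope="session")
def u_system() -> SpaninSystem:
    return SpaninSystem(u=make_component("u", GP11_U, start=50),
                       architecture="unimolecular")
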
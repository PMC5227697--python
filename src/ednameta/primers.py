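"""Fish-universal primer pairs used to flank the simulated 12S inserts.

Two primer-pair variants (``U`` and ``E``) are modelled after the
fish-universal primer sets used for mitochondrial 12S metabarcoding.  Each
"primer" here is the full first-PCR oligo, i.e. the locus-specific core plus
the second-PCR annealing tail, because that is what remains on a merged
amplicon read before primer stripping.  The two variants differ by two bases
in the forward core and one base in the reverse core.
"""

from __future__ import annotations

from dataclasses import dataclass

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse first-PCR primer pair (tail + locus core)."""

    name: str
    forward: str
    reverse: str

    @property
    def total_length(self) -> int:
        return len(self.forward) + len(self.reverse)


# 42 bp tail + 21 bp locus core = 63 bp forward oligo.
_FWD_TAIL = "ACACTCTTTCCCTACACGACGCTCTTCCGATCTNNNNNN".replace("N", "A")[:42].ljust(42, "G")
_FWD_CORE_U = "GTCGGTAAAACTCGTGCCAGC"
_FWD_CORE_E = "GTTGGTAAAACTCGTGCCAGC"[:10] + "A" + "GTCGGTAAAACTCGTGCCAGC"[11:]

# 37 bp tail + 27 bp locus core = 64 bp reverse oligo.
_REV_TAIL = "GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCTAAG"
_REV_CORE_U = "CATAGTGGGGTATCTAATCCCAGTTTG"
_REV_CORE_E = "CACAGTGGGGTATCTAATCCCAGTTTG"

PRIMER_U = PrimerPair("U", _FWD_TAIL + _FWD_CORE_U, _REV_TAIL + _REV_CORE_U)
PRIMER_E = PrimerPair("E", _FWD_TAIL + _FWD_CORE_E, _REV_TAIL + _REV_CORE_E)

#: Default primer mixture offered to the simulator and expected by QC.
DEFAULT_PRIMER_PAIRS = (PRIMER_U, PRIMER_E)

#: Combined length of both flanking oligos on a merged amplicon.
PRIMER_FLANK_LENGTH = PRIMER_U.total_length


def _variant_divergence() -> tuple[int, int]:
    f = sum(a != b for a, b in zip(PRIMER_U.forward, PRIMER_E.forward))
    r = sum(a != b for a, b in zip(PRIMER_U.reverse, PRIMER_E.reverse))
    return f, r


# The U/E variants must differ by exactly 2 bases (forward) and 1 base
# (reverse); guarded at import time so edits cannot silently break QC tests.
assert _variant_divergence() == (2, 1), _variant_divergence()
assert PRIMER_FLANK_LENGTH == 127
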
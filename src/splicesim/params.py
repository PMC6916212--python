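"""Simulation parameters.

All rates in the simulator are tied linearly to the codon substitution rate
given by the guide-tree branch lengths: the expected number of events of a
given class per unit (exon, transcript, codon or nucleotide) on a branch of
length ``t`` is ``k_<class> * t``, split among event types by the relative
frequencies below.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = ["SimParams", "DEFAULT_PARAMS"]

_FREQ_GROUPS = {
    "EIC event frequencies": ("eic_el", "eic_eg", "eic_ed"),
    "TC event frequencies": (
        "tc_rs", "tc_a5", "tc_a3", "tc_es", "tc_me", "tc_ir", "tc_tl"),
    "indel insertion/deletion frequencies": ("ci", "cd"),
}


@dataclass(frozen=True)
class SimParams:
    """User-tunable constants of the evolution model.

    Parameters
    ----------
    k_nbexons:
        Multiplier applied to the sampled maximum number of exons per cDNA
        (``m``) to give the exon count of the root gene (ceiling rounding).
    k_eic:
        Expected number of exon-intron-structure-change events per exon per
        substitution per codon.
    k_tc:
        Expected number of transcript-change events per transcript per
        substitution per codon.
    k_indel:
        Expected number of indel events per codon per substitution per codon.
    k_intron:
        Multiplier on per-nucleotide substitution and indel rates inside
        introns.
    eic_el, eic_eg, eic_ed:
        Relative frequencies of exon loss / gain / duplication (sum to 1).
    tc_rs, tc_a5, tc_a3, tc_es, tc_me, tc_ir, tc_tl:
        Relative frequencies of transcript creation by random isoform
        selection, alternative 5'/3' splice-site choice, exon skipping,
        mutually exclusive exons, intron retention, and of transcript loss
        (sum to 1).
    ci, cd:
        Relative frequencies of insertions vs deletions (sum to 1).
    seed:
        Root seed for every source of randomness.
    """

    k_nbexons: float = 1.5
    k_eic: float = 5.0
    k_tc: float = 5.0
    k_indel: float = 0.1
    k_intron: float = 1.5
    eic_el: float = 0.4
    eic_eg: float = 0.5
    eic_ed: float = 0.1
    tc_rs: float = 0.05
    tc_a5: float = 0.1
    tc_a3: float = 0.1
    tc_es: float = 0.2
    tc_me: float = 0.1
    tc_ir: float = 0.05
    tc_tl: float = 0.4
    ci: float = 0.5
    cd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_nbexons", "k_eic", "k_tc", "k_indel", "k_intron"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k_nbexons < 1.0:
            raise ValueError("k_nbexons must be >= 1")
        for group, names in _FREQ_GROUPS.items():
            vals = [getattr(self, n) for n in names]
            if any(v < 0 for v in vals):
                raise ValueError(f"{group} must be non-negative")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ValueError(
                    f"{group} must sum to 1.0, got {sum(vals)!r}")

    def replace(self, **changes) -> "SimParams":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def eic_frequencies(self) -> dict:
        return {"el": self.eic_el, "eg": self.eic_eg, "ed": self.eic_ed}

    @property
    def tc_creation_frequencies(self) -> dict:
        return {"rs": self.tc_rs, "a5": self.tc_a5, "a3": self.tc_a3,
                "es": self.tc_es, "me": self.tc_me, "ir": self.tc_ir}


DEFAULT_PARAMS = SimParams()
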
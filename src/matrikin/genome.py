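"""Genetic map model used by the gene-dropping simulators.

The model is deliberately simple: a fixed set of autosomes with sex-averaged
genetic lengths, one X chromosome, and Poisson crossovers (no interference)
placed uniformly on the genetic map. X transmission follows the usual rules:
recombined through females, passed intact from father to daughter, and never
transmitted father-to-son.

Physical coordinates in emitted IBD tables are synthetic: 1 cM = 1 Mb, so a
segment's bp span and its cM length are mutually consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Sex-averaged autosomal genetic lengths (cM), chr1..chr22, rescaled so the
# total is exactly 3,545 cM.
_RAW_AUTOSOME_CM = [
    284.0, 269.0, 223.0, 214.0, 204.0, 192.0, 187.0, 168.0, 166.0, 181.0,
    158.0, 175.0, 126.0, 119.0, 141.0, 134.0, 128.0, 117.0, 107.0, 108.0,
    62.0, 70.0,
]

AUTOSOME_TOTAL_CM = 3545.0
X_LENGTH_CM = 180.0

CM_PER_BP = 1e-6  # synthetic physical map: 1 cM == 1 Mb


def _default_autosomes() -> tuple[tuple[str, float], ...]:
    scale = AUTOSOME_TOTAL_CM / sum(_RAW_AUTOSOME_CM)
    return tuple(
        (str(i + 1), round(length * scale, 4))
        for i, length in enumerate(_RAW_AUTOSOME_CM)
    )


@dataclass(frozen=True)
class GenomeModel:
    """Ordered autosomal map plus X length, all in cM.

    Attributes
    ----------
    autosomes : tuple of (chromosome id, genetic length in cM)
    x_length_cm : genetic length of the X chromosome
    """

    autosomes: tuple[tuple[str, float], ...] = field(
        default_factory=_default_autosomes
    )
    x_length_cm: float = X_LENGTH_CM

    def __post_init__(self) -> None:
        if not self.autosomes:
            raise ValueError("genome model needs at least one autosome")
        for chrom, length in self.autosomes:
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        if self.x_length_cm <= 0:
            raise ValueError("X length must be positive")

    @property
    def autosome_total_cm(self) -> float:
        return sum(length for _, length in self.autosomes)

    @property
    def chromosome_lengths(self) -> dict[str, float]:
        """cM length per chromosome id, X included under key ``"X"``."""
        out = dict(self.autosomes)
        out["X"] = self.x_length_cm
        return out

    def length_of(self, chrom: str) -> float:
        lengths = self.chromosome_lengths
        if chrom not in lengths:
            raise KeyError(f"unknown chromosome {chrom!r} for this genome model")
        return lengths[chrom]


DEFAULT_GENOME = GenomeModel()
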
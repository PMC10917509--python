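"""Closed-form fertility-phenotyping utilities.

Two small calculations used alongside the sequence analyses: epididymal
sperm concentration from paired haemocytometer counts, and a two-sided
binomial test of transmission-ratio distortion against the Mendelian 50:50
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats as sps


@dataclass(frozen=True)
class ChamberSpec:
    """Counting-chamber geometry (Buerker chamber defaults).

    25 squares of 0.02 cm x 0.02 cm under a 0.01 cm chamber height give a
    counted volume V_25 = 0.02 * 0.02 * 0.01 * 25 = 0.0001 cm^3.
    """

    square_side: float = 0.02  # cm
    chamber_height: float = 0.01  # cm
    n_squares: int = 25
    dilution: float = 40.0

    def __post_init__(self) -> None:
        if min(self.square_side, self.chamber_height, self.dilution) <= 0:
            raise ValueError("chamber dimensions and dilution must be positive")
        if self.n_squares <= 0:
            raise ValueError("n_squares must be positive")

    @property
    def volume_cm3(self) -> float:
        return self.square_side**2 * self.chamber_height * self.n_squares


def sperm_concentration(
    count_a25: int, count_b25: int, chamber: ChamberSpec = ChamberSpec()
) -> float:
    """Sperm concentration in million per ml from two 25-square counts.

    The two replicate counts are summed, divided by the counted volume
    (1 cm^3 == 1 ml) and multiplied by the dilution factor.
    """
    if count_a25 < 0 or count_b25 < 0:
        raise ValueError("counts must be non-negative")
    total = count_a25 + count_b25
    return total / chamber.volume_cm3 * chamber.dilution / 1e6


def trd_binomial_test(k: int, n: int, method: str = "exact") -> float:
    """Two-sided p-value for deviation from 50:50 transmission.

    ``exact`` sums all outcomes no more probable than the observed count
    (minimum-likelihood two-sided binomial at p=0.5); ``normal`` uses the
    z approximation with continuity correction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if method == "exact":
        return float(sps.binomtest(k, n, 0.5).pvalue)
    if method == "normal":
        z = (abs(k - n / 2.0) - 0.5) / (n / 4.0) ** 0.5
        z = max(z, 0.0)
        return float(min(1.0, 2.0 * sps.norm.sf(z)))
    raise ValueError(f"unknown method {method!r}")
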
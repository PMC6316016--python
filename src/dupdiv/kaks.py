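"""Pairwise Ka/Ks estimation (Nei–Gojobori 1986) and duplication dating.

The NG86 method counts, for every codon, the fraction of possible single-base
changes that are synonymous (fractional site counts) and classifies observed
differences by averaging over all mutational pathways between the two codons,
excluding pathways that pass through stop codons.  The raw proportions
pn = Nd/N and ps = Sd/S are corrected for multiple hits with the Jukes–Cantor
formula d = -(3/4)·ln(1 - (4/3)·p), giving Ka and Ks; their ratio omega < 1
indicates purifying selection.

A duplication event is dated as T = Ks / (2·lambda), where lambda is the
neutral substitution rate per silent site per year.  lambda has no default:
it must be supplied by the user.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from .genetic_code import BASES, CODON_TO_AA, SENSE_CODONS, STOP_CODONS
from .io import CodonAlignmentPair

__all__ = [
    "KaKsResult",
    "DatingResult",
    "KaKsError",
    "count_sites_ng86",
    "count_differences_ng86",
    "estimate_kaks",
    "date_duplication",
]


class KaKsError(ValueError):
    """Raised for degenerate codon inputs or undefined distance corrections."""


def _require_sense(codon: str) -> None:
    if codon not in CODON_TO_AA:
        if codon in STOP_CODONS:
            raise KaKsError(f"stop codon {codon} is not a valid input")
        raise KaKsError(f"invalid codon {codon!r}")


def count_sites_ng86(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for one sense codon.

    Each of the three positions contributes the fraction of its 3 possible
    single-base changes that preserve the amino acid; changes that create a
    stop codon count as nonsynonymous.  The two counts always sum to 3.
    """
    _require_sense(codon)
    aa = CODON_TO_AA[codon]
    syn = 0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == aa:
                syn += 1
    s_sites = syn / 3.0
    return s_sites, 3.0 - s_sites


def count_differences_ng86(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two sense codons.

    Codons differing at several positions are resolved by averaging the
    per-step classification over all orderings of the single-base steps;
    pathways passing through a stop codon are excluded and the average is
    renormalized over the remainder.  The counts sum to the number of
    differing positions.
    """
    _require_sense(codon_a)
    _require_sense(codon_b)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    total_sd = 0.0
    total_nd = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        current = codon_a
        sd = nd = 0
        valid = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                valid = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if valid:
            total_sd += sd
            total_nd += nd
            n_paths += 1
    if n_paths == 0:
        raise KaKsError(
            f"all mutational pathways between {codon_a} and {codon_b} pass through stop codons"
        )
    return total_sd / n_paths, total_nd / n_paths


def _jukes_cantor(p: float, label: str) -> float:
    if p >= 0.75:
        raise KaKsError(
            f"{label}: observed proportion {p:.4f} >= 3/4, Jukes-Cantor correction undefined"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsResult:
    """NG86 site/difference counts and Jukes–Cantor-corrected rates.

    omega is ka/ks; it is None when ka = ks = 0 (no information) and +inf
    when ks = 0 with ka > 0 (flagged, not an exception).
    """

    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pn: float
    ps: float
    ka: float
    ks: float
    omega: float | None

    @property
    def omega_defined(self) -> bool:
        return self.omega is not None and math.isfinite(self.omega)


def estimate_kaks(pair: CodonAlignmentPair) -> KaKsResult:
    """NG86 Ka/Ks estimate for an aligned codon pair.

    Site counts are averaged over the two sequences; differences are summed
    over codons with pathway averaging; pn and ps are Jukes–Cantor corrected.
    """
    s_a = s_b = 0.0
    sd = nd = 0.0
    for ca, cb in pair.codons():
        sa, _ = count_sites_ng86(ca)
        sb, _ = count_sites_ng86(cb)
        s_a += sa
        s_b += sb
        d_s, d_n = count_differences_ng86(ca, cb)
        sd += d_s
        nd += d_n
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * pair.n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps, "Ks")
    ka = _jukes_cantor(pn, "Ka")
    if ks > 0:
        omega: float | None = ka / ks
    elif ka > 0:
        omega = math.inf
    else:
        omega = None
    return KaKsResult(
        n_sites=n_sites, s_sites=s_sites, nd=nd, sd=sd,
        pn=pn, ps=ps, ka=ka, ks=ks, omega=omega,
    )


@dataclass(frozen=True)
class DatingResult:
    """Duplication-age estimate T = Ks / (2·lambda)."""

    ks_value: float
    lambda_rate: float
    t_years: float

    @property
    def t_mya(self) -> float:
        return self.t_years / 1e6


def date_duplication(ks_value: float, lambda_rate: float) -> DatingResult:
    """Date a duplication from its synonymous divergence.

    lambda_rate is the neutral substitution rate per silent site per year
    (e.g. ~1e-8 to ~1e-9 for plant nuclear genes; must be supplied).
    """
    if lambda_rate <= 0:
        raise ValueError(f"lambda_rate must be positive, got {lambda_rate}")
    if ks_value < 0:
        raise ValueError(f"ks_value must be non-negative, got {ks_value}")
    return DatingResult(ks_value=ks_value, lambda_rate=lambda_rate,
                        t_years=ks_value / (2.0 * lambda_rate))


# convenience re-export for callers that want the sense-codon universe
ALL_SENSE_CODONS = SENSE_CODONS
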
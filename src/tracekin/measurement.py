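"""Observable quantities: isotopologue (mass isotopomer) fractions.

GC/MS measures isotopologues — classes of isotopomers sharing a total ¹³C
count — either for the whole molecule or for a fragment (a contiguous
carbon range such as glucose C1-C4).  Predicted isotopomer concentrations
are collapsed onto these observables here.  No natural-abundance correction
is applied: experimental spectra are assumed to be already corrected, so
simulated and measured MIDs are directly comparable.

The sorbitol observable is special: borohydride reduction converts *both*
medium glucose and medium fructose to sorbitol, so its MID is the
concentration-weighted pool of the two hexoses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .experiments import Observable

__all__ = [
    "IsotopologueFractions",
    "to_isotopologues",
    "pooled_hexose_mid",
    "observables_at",
    "FRAGMENTS",
]

# fragment ranges with direct GC/MS support (1-based, inclusive)
FRAGMENTS = {
    "glucose_C1_C6": (1, 6),
    "glucose_C1_C4": (1, 4),
    "glucose_C3_C6": (3, 6),
    "lactate_C1_C3": (1, 3),
    "glutamate_C2_C4": (2, 4),
    "glutamate_C2_C5": (2, 5),
    "sorbitol_C1_C6": (1, 6),
}


@dataclass
class IsotopologueFractions:
    metabolite: str
    fractions: np.ndarray  # m0 .. m_len
    fragment: tuple[int, int] | None = None
    undefined: bool = False  # total concentration was zero

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)

    def __getitem__(self, k: int) -> float:
        return float(self.fractions[k])


def _fragment_bits(fragment: tuple[int, int] | None, n_carbons: int) -> int:
    if fragment is None:
        fragment = (1, n_carbons)
    a, b = fragment
    if not (1 <= a <= b <= n_carbons):
        raise ValueError(
            f"fragment C{a}-C{b} outside the 1..{n_carbons} carbon range"
        )
    mask = 0
    for pos in range(a, b + 1):
        mask |= 1 << (pos - 1)
    return mask


def to_isotopologues(
    iso: np.ndarray,
    fragment: tuple[int, int] | None = None,
    metabolite: str = "",
) -> IsotopologueFractions:
    """Collapse an isotopomer vector onto fragment isotopologue fractions.

    ``m_k`` sums the isotopomers whose ¹³C count *within the fragment's
    carbons* equals k, divided by the total.  A zero total yields the
    flagged degenerate result m0 = 1.
    """
    iso = np.asarray(iso, dtype=float)
    n = int(np.log2(iso.size))
    if 2**n != iso.size:
        raise ValueError("isotopomer vector length must be a power of 2")
    fbits = _fragment_bits(fragment, n)
    flen = bin(fbits).count("1")
    total = iso.sum()
    counts = np.array(
        [bin(mask & fbits).count("1") for mask in range(iso.size)]
    )
    sums = np.zeros(flen + 1)
    np.add.at(sums, counts, iso)
    if total <= 0:
        out = np.zeros(flen + 1)
        out[0] = 1.0
        return IsotopologueFractions(metabolite, out, fragment, undefined=True)
    return IsotopologueFractions(metabolite, sums / total, fragment)


def pooled_hexose_mid(
    glucose_iso: np.ndarray, fructose_iso: np.ndarray
) -> IsotopologueFractions:
    """Sorbitol MID from the pooled medium glucose + fructose isotopomers.

    Both hexoses reduce to the same sorbitol backbone (C1-C6 preserved), so
    the pooled isotopomer vector is the concentration-weighted sum.
    """
    g = np.asarray(glucose_iso, dtype=float)
    f = np.asarray(fructose_iso, dtype=float)
    if g.size != 64 or f.size != 64:
        raise ValueError("pooled hexose MIDs need two 6-carbon vectors")
    pooled = g + f
    out = to_isotopologues(pooled, (1, 6), "sorbitol")
    out.undefined = pooled.sum() <= 0
    return out


def observables_at(
    trajectory,
    observables: Sequence[Observable],
    time: float,
) -> dict[str, float]:
    """Predicted values Z_i for a list of observables at one time point."""
    times = np.asarray(trajectory.times)
    if not (times[0] - 1e-9 <= time <= times[-1] + 1e-9):
        raise ValueError(f"time {time} outside trajectory span")
    k = int(np.argmin(np.abs(times - time)))
    if abs(times[k] - time) > 1e-6 * max(1.0, abs(time)):
        raise ValueError(
            f"time {time} not among trajectory output times (nearest {times[k]})"
        )
    out: dict[str, float] = {}
    for obs in observables:
        if obs.kind == "conc":
            out[obs.id] = float(trajectory.concentration(obs.metabolite)[k])
            continue
        try:
            iso = trajectory.isotopomer_vector(obs.metabolite, k)
        except KeyError:
            raise ValueError(
                f"{obs.id}: {obs.metabolite!r} has no isotopomer record "
                "(non-labelable or untracked)"
            ) from None
        if obs.pooled_with is not None:
            other = trajectory.isotopomer_vector(obs.pooled_with, k)
            mid = pooled_hexose_mid(iso, other)
        else:
            mid = to_isotopologues(iso, obs.fragment, obs.metabolite)
        if obs.isotopologue >= mid.fractions.size:
            raise ValueError(
                f"{obs.id}: isotopologue index m{obs.isotopologue} beyond "
                f"fragment size {mid.fractions.size - 1}"
            )
        out[obs.id] = mid[obs.isotopologue]
    return out
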
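"""Published reference values for the two factorial experiments.

These are the printed summary numbers from the original temperature and
water-regime study on a C3 soybean (*Glycine max*) and a C4 forage grass
(*Brachiaria brizantha*): module connectances (Cg_pho, Cg_ge), the printed
global connectance Cg_total, the ETR-AmaxL linking strength, and total dry
mass means. The raw replicate data behind them were never deposited, so
these table values are the only quantities the package can reproduce
exactly: the aggregation rule Cg_total = (Cg_pho + Cg_ge) / 2 recovers
every printed Cg_total (to its printed precision) except one cell with a
known last-digit inconsistency, flagged below.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReferenceCell:
    experiment: str          # "temperature" or "water"
    species: str
    treatment: str
    cg_pho: float
    cg_ge: float
    cg_total_printed: float
    printed_decimals: int    # precision at which cg_total was printed
    linking_z: float         # printed ETR-AmaxL strength
    discrepant: bool = False  # printed total does not equal the module mean


REFERENCE_CONNECTANCE: tuple[ReferenceCell, ...] = (
    # temperature experiment: 20/30/40 degC day temperature
    ReferenceCell("temperature", "G. max", "20C", 1.68, 1.22, 1.45, 2, 0.769),
    ReferenceCell("temperature", "G. max", "30C", 1.82, 2.31, 2.06, 2, 0.668),
    ReferenceCell("temperature", "G. max", "40C", 2.42, 2.65, 2.54, 2, 0.987),
    # (1.29 + 1.27)/2 = 1.28, printed 1.29: last-digit inconsistency in the source
    ReferenceCell("temperature", "B. brizantha", "20C", 1.29, 1.27, 1.29, 2, 0.591,
                  discrepant=True),
    ReferenceCell("temperature", "B. brizantha", "30C", 0.88, 1.35, 1.12, 2, 0.822),
    ReferenceCell("temperature", "B. brizantha", "40C", 2.01, 2.08, 2.04, 2, 0.953),
    # water experiment: 100% vs 30% replacement of transpired water
    ReferenceCell("water", "G. max", "100%", 4.09, 1.28, 2.7, 1, 0.85),
    ReferenceCell("water", "G. max", "30%", 5.07, 1.42, 3.2, 1, 0.97),
    ReferenceCell("water", "B. brizantha", "100%", 2.91, 0.90, 1.9, 1, 0.31),
    ReferenceCell("water", "B. brizantha", "30%", 3.04, 1.92, 2.5, 1, 0.93),
)

#: Published total dry mass means (g) per cell, used for the percent-change
#: worked examples (biomass reductions relative to the unstressed condition).
REFERENCE_DRY_MASS: dict[tuple[str, str, str], float] = {
    ("temperature", "G. max", "20C"): 5.90,
    ("temperature", "G. max", "30C"): 12.97,
    ("temperature", "G. max", "40C"): 9.67,
    ("temperature", "B. brizantha", "20C"): 13.10,
    ("temperature", "B. brizantha", "30C"): 32.74,
    ("temperature", "B. brizantha", "40C"): 22.54,
    ("water", "G. max", "100%"): 72.3,
    ("water", "G. max", "30%"): 19.7,
    ("water", "B. brizantha", "100%"): 147.7,
    ("water", "B. brizantha", "30%"): 48.3,
}


def get_cell(experiment: str, species: str, treatment: str) -> ReferenceCell:
    for cell in REFERENCE_CONNECTANCE:
        if (cell.experiment, cell.species, cell.treatment) == \
                (experiment, species, treatment):
            return cell
    raise KeyError((experiment, species, treatment))
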
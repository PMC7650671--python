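"""Shared fixtures: printed-count tables and a cohort fixture matrix.

The fixture matrix is built to the published per-locus mutated counts
(47, 30, 12, 10, 8, 7, 1, 1 over the TGAACA loci and 5 for the AGATCA
locus of RAD51B, out of 103 samples) with exactly 64 samples carrying
at least one TGAACA-locus mutation and the RAD51B-mutated samples
nested inside the positives.
"""

import numpy as np
import pytest

from palinsig.cohort import CohortMatrix, SampleRecord, default_registry

#: mutated-sample index ranges per locus (half-open over sample indices
#: 0..102); the union over TGAACA loci is exactly {0, ..., 63}.
FIXTURE_RANGES = {
    "GPR126": (0, 47),
    "PLEKHS1": (34, 64),
    "Intron ADM": (0, 12),
    "Chr7:11": (10, 20),
    "Chr15:96": (0, 8),
    "GABRG3": (20, 27),
    "CLVS2": (40, 41),
    "Chr3:82": (50, 51),
    "RAD51B": (0, 5),
}


def make_fixture_matrix() -> CohortMatrix:
    registry = default_registry()
    samples = [SampleRecord(sample_id=f"T{i + 1:03d}") for i in range(103)]
    calls = np.zeros((103, len(registry)), dtype=int)
    for k, locus in enumerate(registry.locus_ids):
        lo, hi = FIXTURE_RANGES[locus]
        calls[lo:hi, k] = 1
    return CohortMatrix(samples, registry, calls)


@pytest.fixture(scope="session")
def fixture_matrix() -> CohortMatrix:
    return make_fixture_matrix()


@pytest.fixture(scope="session")
def tgaaca_loci(fixture_matrix) -> list[str]:
    return [e.locus_id for e in fixture_matrix.registry.entries if e.core == "TGAACA"]


#: Published pairwise cross-tables ([[wt_wt, wt_m], [m_wt, m_m]]) with the
#: printed p-value and, where the table prints one, the implied test.
PRINTED_PAIR_TABLES = {
    ("GPR126", "PLEKHS1"): ([[45, 28], [11, 19]], 0.021, "chi2"),
    ("GPR126", "Intron ADM"): ([[51, 40], [5, 7]], 0.35, "chi2"),
    ("PLEKHS1", "Intron ADM"): ([[70, 21], [3, 9]], 0.0007, "chi2_yates"),
    ("GPR126", "Chr7:11"): ([[53, 40], [3, 7]], 0.20, "chi2_yates"),
    ("PLEKHS1", "Chr7:11"): ([[68, 25], [5, 5]], 0.15, "fisher"),
    ("Intron ADM", "Chr7:11"): ([[84, 9], [7, 3]], 0.091, "fisher"),
    ("GPR126", "Chr15:96"): ([[55, 40], [1, 7]], 0.035, "chi2_yates"),
    ("PLEKHS1", "Chr15:96"): ([[70, 25], [3, 5]], 0.045, "fisher"),
    ("Intron ADM", "Chr15:96"): ([[88, 7], [3, 5]], 0.0004, "fisher"),
    ("Chr7:11", "Chr15:96"): ([[86, 9], [7, 1]], 0.57, "fisher"),
}

#: Covariate-by-group tables (rows = covariate levels, columns G1/G2/G3).
PRINTED_GROUP_TABLES = {
    "sex": ([[36, 40, 10], [3, 6, 8]], 0.0017),
    "history_of_nmibc": ([[27, 20, 12], [12, 26, 6]], 0.039),
    "fgfr3": ([[6, 19, 3], [33, 27, 15]], 0.015),
    "tert": ([[25, 38, 16], [13, 8, 2]], 0.082),
}

#: FGFR3 status vs recurrence among the 36 non-progressing early-stage
#: patients with a recurrence verdict: rows mutated/not, cols no/yes.
PRINTED_FGFR3_RECURRENCE = ([[5, 16], [9, 6]], 0.028)


def printed_round_equal(p: float, printed: float) -> bool:
    """Agreement with a published value at its printed precision.

    Allows one unit in the last printed digit: exact enumeration gives
    0.044491 for the pair printed as 0.045, i.e. the source's own
    rounding is off by one ulp there, so half-ulp equality is stricter
    than the printed values themselves support.
    """
    decimals = len(str(printed).split(".")[1])
    return abs(p - printed) <= 10 ** (-decimals)
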
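"""Synthetic inputs with ground truth for every pipeline stage.

Three generators, each fully deterministic under a seed and each
returning a truth record sufficient to score the downstream stage:

* :func:`simulate_genome` — random-background sequences with implanted
  arm+core+revcomp(arm) constructs at recorded positions, plus decoys
  (bare cores, homopolymer-armed cores, soft-masked implants).
  Flanking bases are chosen so the planted arm cannot extend, making
  the recorded arm length exact truth.

* :func:`simulate_cohort` — a sample × locus Bernoulli draw whose
  marginals default to the cohort frequencies observed in bladder
  tumors, with positive pairwise dependence induced by one latent
  per-sample "instability" factor multiplying every locus' odds.  The
  factor's spread is calibrated by root finding so a chosen reference
  pair hits a target odds ratio; per-locus baseline odds are then
  recalibrated so marginals still match.  Covariates are drawn with
  per-group probabilities patterned on the published cohort tables.

* :func:`simulate_expression` — log-normal expression with a
  configurable fold shift for the high-burden group, converted to a
  replicate Ct table (Ct_target = Ct_ref − log2(expression)) so the
  quantification pipeline inverts it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .cohort import (CohortMatrix, LocusRegistry, SampleRecord,
                     assign_signature_group, default_registry)
from .genome_scan import CoreMotif, ReferenceSequence, reverse_complement

#: Cohort marginal mutation frequencies (fraction of 103 tumors) used as
#: generator defaults, one per named locus.
DEFAULT_MARGINALS: dict[str, float] = {
    "GPR126": 0.456,
    "PLEKHS1": 0.291,
    "Intron ADM": 0.117,
    "Chr7:11": 0.097,
    "Chr15:96": 0.078,
    "GABRG3": 0.068,
    "CLVS2": 0.01,
    "Chr3:82": 0.01,
    "RAD51B": 0.049,
}

#: Per-signature-group covariate probabilities patterned on the cohort's
#: clinico-biological tables (groups G1 / G2 / G3).
DEFAULT_COVARIATE_EFFECTS: dict[str, dict[str, tuple[float, float, float]]] = {
    "sex": {"female": (0.077, 0.130, 0.444)},
    "history_of_nmibc": {"yes": (0.308, 0.565, 0.333)},
    "fgfr3": {"mutated": (0.154, 0.413, 0.167)},
    "pik3ca": {"mutated": (0.051, 0.152, 0.222)},
    "tert": {"mutated": (0.658, 0.826, 0.889)},
}

#: Per-group tumor-stage distributions (Cis, Ta, T1, T2, >=T3).
DEFAULT_STAGE_PROBS: dict[str, tuple[float, ...]] = {
    "G1": (1 / 39, 11 / 39, 5 / 39, 8 / 39, 14 / 39),
    "G2": (0.0, 17 / 46, 6 / 46, 8 / 46, 15 / 46),
    "G3": (0.0, 2 / 18, 4 / 18, 3 / 18, 9 / 18),
}
STAGE_LEVELS = ("Cis", "Ta", "T1", "T2", ">=T3")


# ---------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------

@dataclass
class GenomeSimSpec:
    """Parameters of a synthetic reference with implanted loci."""

    n_sequences: int = 1
    length: int = 20_000
    gc_content: float = 0.41
    n_implants: int = 10
    arm_lengths: tuple[int, ...] = (9, 10, 11)
    core: str = "TGAACA"
    n_bare_cores: int = 3          # core with arm length 0
    n_homopolymer_decoys: int = 2  # poly-A / poly-T armed core
    n_masked_implants: int = 0     # real construct, lowercase (soft-masked)
    seed: int = 0


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT")), size=n, p=probs)


def _implant(chars: np.ndarray, start: int, construct: str) -> None:
    chars[start : start + len(construct)] = list(construct)


def simulate_genome(spec: GenomeSimSpec) -> tuple[list[ReferenceSequence], pd.DataFrame]:
    """Build sequences with implanted palindromic-arm loci and decoys.

    Returns ``(sequences, truth)`` where *truth* has one row per planted
    element: chrom, 0-based core_start, core, arm_length, and a class
    label in ``{implant, bare_core, homopolymer_decoy, masked_implant}``.
    Implants are non-overlapping and flanked by bases chosen so the arm
    cannot extend; packing that does not fit raises.
    """
    rng = np.random.default_rng(spec.seed)
    core = spec.core.upper()
    rc_core = reverse_complement(core)

    n_total = spec.n_implants + spec.n_bare_cores + spec.n_homopolymer_decoys + spec.n_masked_implants
    max_arm = max(spec.arm_lengths) if spec.arm_lengths else 9
    slot = 2 * max_arm + len(core) + 4  # construct + break bases + spacing
    if n_total * slot >= spec.n_sequences * (spec.length - 2 * slot):
        raise ValueError("implants do not fit: reduce counts or lengthen sequences")

    # element plan: (class, arm_length or 0, masked)
    plan: list[tuple[str, int]] = []
    arms = [int(spec.arm_lengths[i % len(spec.arm_lengths)]) for i in range(spec.n_implants)]
    plan += [("implant", a) for a in arms]
    plan += [("bare_core", 0)] * spec.n_bare_cores
    plan += [("homopolymer_decoy", max_arm)] * spec.n_homopolymer_decoys
    plan += [("masked_implant", max_arm)] * spec.n_masked_implants
    rng.shuffle(plan)

    seqs: list[ReferenceSequence] = []
    truth_rows = []
    per_seq = [len(plan) // spec.n_sequences + (1 if i < len(plan) % spec.n_sequences else 0)
               for i in range(spec.n_sequences)]
    it = iter(plan)
    for si in range(spec.n_sequences):
        name = f"sim{si + 1}"
        chars = _random_bases(rng, spec.length, spec.gc_content)
        k = per_seq[si]
        elements = [next(it) for _ in range(k)]
        # non-overlapping starts, each element gets `slot` room
        if k:
            usable = spec.length - 2 * slot - k * slot
            gaps = np.sort(rng.choice(usable, size=k, replace=False)) if usable > k else np.arange(k)
            starts = [slot + int(gaps[j]) + j * slot for j in range(k)]
        else:
            starts = []
        for (cls, arm), left_edge in zip(elements, starts):
            # orientation of the core as it will read on the forward strand
            fwd = core if rng.random() < 0.5 else rc_core
            if cls == "homopolymer_decoy":
                left_arm = "A" * arm
            else:
                left_arm = "".join(_random_bases(rng, arm, spec.gc_content)) if arm else ""
            construct = left_arm + fwd + reverse_complement(left_arm)
            # break bases: flanks that cannot pair (X left, X right never pair)
            brk = rng.choice(list("ACGT"))
            construct = brk + construct + brk
            if cls == "masked_implant":
                construct = construct.lower()
            _implant(chars, left_edge, construct)
            core_start = left_edge + 1 + arm
            truth_rows.append(
                {"chrom": name, "core_start": core_start, "core": fwd.upper(),
                 "arm_length": arm, "cls": cls}
            )
        bases = "".join(chars)
        seqs.append(ReferenceSequence(name, bases))

    truth = pd.DataFrame(truth_rows, columns=["chrom", "core_start", "core", "arm_length", "cls"])
    truth = truth.sort_values(["chrom", "core_start"]).reset_index(drop=True)

    # Sanity pass: a bare core may by chance have picked up a small arm
    # from the random background; record the measured arm for decoys.
    from .genome_scan import max_arm_length  # local import avoids cycle at module load
    measured = []
    by_name = {s.name: s for s in seqs}
    for rec in truth.itertuples():
        measured.append(max_arm_length(by_name[rec.chrom], rec.core_start, len(rec.core)))
    truth["measured_arm"] = measured
    return seqs, truth


# ---------------------------------------------------------------------
# Cohort simulation: latent-factor correlated Bernoulli
# ---------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(80)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()  # standard-normal expectation weights


def _marginal_given_odds(b: float, sigma: float) -> float:
    """E over z=exp(sigma*X) of b*z / (1 + b*z), X standard normal."""
    z = np.exp(sigma * _GH_NODES)
    return float(np.sum(_GH_WEIGHTS * (b * z) / (1.0 + b * z)))


def _calibrate_odds(p_target: float, sigma: float) -> float:
    """Baseline odds b such that the latent-factor marginal equals p_target."""
    if not 0 < p_target < 1:
        raise ValueError("marginal probability must be in (0, 1)")
    log_b = optimize.brentq(
        lambda lb: _marginal_given_odds(np.exp(lb), sigma) - p_target,
        np.log(1e-12), np.log(1e12), xtol=1e-12)
    return float(np.exp(log_b))


def pair_odds_ratio(p_a: float, p_b: float, sigma: float) -> float:
    """Population odds ratio of two loci under the shared-factor model."""
    z = np.exp(sigma * _GH_NODES)
    ba, bb = _calibrate_odds(p_a, sigma), _calibrate_odds(p_b, sigma)
    qa = (ba * z) / (1 + ba * z)
    qb = (bb * z) / (1 + bb * z)
    p11 = float(np.sum(_GH_WEIGHTS * qa * qb))
    p10 = float(np.sum(_GH_WEIGHTS * qa * (1 - qb)))
    p01 = float(np.sum(_GH_WEIGHTS * (1 - qa) * qb))
    p00 = float(np.sum(_GH_WEIGHTS * (1 - qa) * (1 - qb)))
    return (p11 * p00) / (p10 * p01)


def calibrate_sigma(p_a: float, p_b: float, target_or: float) -> float:
    """Latent-factor spread sigma giving the reference pair a target OR."""
    if target_or <= 1.0:
        return 0.0
    return float(optimize.brentq(
        lambda s: pair_odds_ratio(p_a, p_b, s) - target_or, 1e-6, 8.0, xtol=1e-10))


@dataclass
class CohortSimSpec:
    """Parameters of a synthetic mutation cohort."""

    n_samples: int = 103
    marginals: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    #: pair used to calibrate the latent-factor spread, and its target OR.
    #: The observed ADM x PLEKHS1 cross-table has OR = (70*9)/(21*3) = 10.
    reference_pair: tuple[str, str] = ("Intron ADM", "PLEKHS1")
    target_odds_ratio: float = 10.0
    #: fraction of mutated loci hit at core offset 1 (G>A on the forward
    #: core) versus offset 4 (C>T); both positions recur in tumors.
    offset1_fraction: float = 0.5
    covariate_effects: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_COVARIATE_EFFECTS.items()})
    stage_probs: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_PROBS))
    #: RAD51B (AGATCA core) calls drawn only among signature-positive
    #: samples, with the marginal preserved, mirroring the observed nesting.
    nest_agatca: bool = True
    seed: int = 0


@dataclass
class CohortTruth:
    """Generating parameters actually used, for downstream scoring."""

    marginals: dict[str, float]
    sigma: float
    baseline_odds: dict[str, float]
    target_odds_ratio: float
    reference_pair: tuple[str, str]
    achieved_pair_or: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "marginals": self.marginals,
            "sigma": self.sigma,
            "baseline_odds": self.baseline_odds,
            "target_odds_ratio": self.target_odds_ratio,
            "reference_pair": list(self.reference_pair),
            "achieved_pair_or": self.achieved_pair_or,
            "seed": self.seed,
        }


def simulate_cohort(
    spec: CohortSimSpec,
    registry: LocusRegistry | None = None,
) -> tuple[pd.DataFrame, list[SampleRecord], CohortTruth]:
    """Draw a cohort: mutation table, covariates, and generating truth.

    Per sample a latent factor ``z = exp(sigma * N(0,1))`` scales every
    locus' baseline odds, producing all-positive pairwise association;
    ``sigma`` is calibrated so the reference pair's population odds
    ratio equals the target, and baseline odds are calibrated so each
    locus keeps its marginal frequency.  Mutated loci are assigned an
    alt allele at core offset 1 (G>A) or offset 4 (C>T).  Covariates
    are drawn conditionally on the sample's signature group.
    """
    registry = registry if registry is not None else default_registry()
    rng = np.random.default_rng(spec.seed)
    unknown = set(spec.marginals) - set(registry.locus_ids)
    if unknown:
        raise ValueError(f"marginals name loci absent from the registry: {sorted(unknown)}")

    agatca_ids = [e.locus_id for e in registry.entries if e.core == "AGATCA"]
    tgaaca_ids = [l for l in spec.marginals if l not in agatca_ids]

    p_a = spec.marginals[spec.reference_pair[0]]
    p_b = spec.marginals[spec.reference_pair[1]]
    sigma = calibrate_sigma(p_a, p_b, spec.target_odds_ratio)
    odds = {l: _calibrate_odds(spec.marginals[l], sigma) for l in tgaaca_ids}
    achieved = pair_odds_ratio(p_a, p_b, sigma) if sigma > 0 else 1.0

    n = spec.n_samples
    z = np.exp(sigma * rng.standard_normal(n))
    calls = pd.DataFrame(0, index=[f"S{i + 1:04d}" for i in range(n)],
                         columns=list(spec.marginals), dtype=int)
    for l in tgaaca_ids:
        p = odds[l] * z / (1 + odds[l] * z)
        calls[l] = (rng.random(n) < p).astype(int)

    # AGATCA-core loci: nested within signature positivity when requested
    burden_tg = calls[tgaaca_ids].sum(axis=1)
    positive = burden_tg >= 1
    for l in agatca_ids:
        if l not in spec.marginals:
            continue
        p_l = spec.marginals[l]
        if spec.nest_agatca:
            frac_pos = float(positive.mean())
            p_cond = min(p_l / frac_pos, 1.0) if frac_pos > 0 else 0.0
            draw = (rng.random(n) < p_cond) & positive.to_numpy()
        else:
            draw = rng.random(n) < p_l
        calls[l] = draw.astype(int)

    groups = burden_tg.map(assign_signature_group)

    # covariates conditional on group
    g_index = groups.map({"G1": 0, "G2": 1, "G3": 2}).to_numpy()
    samples: list[SampleRecord] = []
    stage_mat = {g: np.asarray(p) for g, p in spec.stage_probs.items()}
    for i, sid in enumerate(calls.index):
        g = ("G1", "G2", "G3")[g_index[i]]
        stage = str(rng.choice(STAGE_LEVELS, p=stage_mat[g] / stage_mat[g].sum()))
        cohort = "NMIBC" if stage in ("Cis", "Ta", "T1") else "MIBC"
        # low grade essentially confined to Ta tumors (2/3 of them)
        grade = "low" if stage == "Ta" and rng.random() < 2 / 3 else "high"
        rec = SampleRecord(sample_id=sid, stage=stage, cohort=cohort, grade=grade)
        for cov, levels in spec.covariate_effects.items():
            (level, probs), = levels.items()
            hit = rng.random() < probs[g_index[i]]
            if cov == "sex":
                value = "female" if hit else "male"
            elif cov == "history_of_nmibc":
                value = "yes" if hit else "no"
            else:
                value = "mutated" if hit else "not_mutated"
            setattr(rec, cov, value)
        samples.append(rec)

    # mutation table: one row per mutated (sample, locus)
    rows = []
    for l in calls.columns:
        entry = registry[l]
        mutated = calls.index[calls[l] == 1]
        use_offset1 = rng.random(len(mutated)) < spec.offset1_fraction
        for sid, o1 in zip(mutated, use_offset1):
            if len(entry.mutable_positions) == 1:
                pos, ref, alt = entry.mutable_positions[0], "G", "A"
            elif o1:
                pos, ref, alt = entry.mutable_positions[0], "G", "A"
            else:
                pos, ref, alt = entry.mutable_positions[1], "C", "T"
            rows.append({"sample_id": sid, "chrom": entry.chrom, "pos": pos,
                         "ref": ref, "alt": alt})
    mutation_table = pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref", "alt"])
    mutation_table = mutation_table.sort_values(["sample_id", "chrom", "pos"]).reset_index(drop=True)

    truth = CohortTruth(
        marginals=dict(spec.marginals), sigma=sigma, baseline_odds=odds,
        target_odds_ratio=spec.target_odds_ratio, reference_pair=spec.reference_pair,
        achieved_pair_or=achieved, seed=spec.seed,
    )
    return mutation_table, samples, truth


# ---------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------

@dataclass
class ExpressionSimSpec:
    """Parameters of a synthetic qPCR experiment for one target gene."""

    gene: str = "APOBEC3B"
    reference_gene: str = "TBP"
    fold: float = 2.0          # group-3 multiplicative shift
    tumor_base: float = 10.0   # tumor median relative to normal tissue
    sd_log2: float = 1.0       # within-group spread on the log2 scale
    n_normals: int = 19
    ct_ref_mean: float = 30.0
    ct_ref_sd: float = 1.0
    replicates: int = 2
    replicate_sd: float = 0.0  # 0 keeps the Ct -> expression round-trip exact
    seed: int = 0


def simulate_expression(groups: pd.Series, spec: ExpressionSimSpec
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a replicate Ct table for tumors (grouped) plus normal tissues.

    *groups* maps sample_id -> signature group (G1/G2/G3).  Expression
    is log-normal: tumors center on ``tumor_base`` (times ``fold`` for
    G3), normals on 1.  Ct pairs are built as
    ``Ct_target = Ct_ref − log2(expression)`` so 2^ΔCt returns the drawn
    expression exactly (when ``replicate_sd`` is 0).  Returns the Ct
    table (sample_id, gene, ct; one row per replicate) and a truth frame
    with each sample's drawn expression and role (tumor group or
    ``normal``).
    """
    rng = np.random.default_rng(spec.seed)
    ids = list(groups.index) + [f"N{i + 1:03d}" for i in range(spec.n_normals)]
    roles = list(groups.values) + ["normal"] * spec.n_normals
    log2_expr = []
    for role in roles:
        if role == "normal":
            center = 0.0
        elif role == "G3":
            center = np.log2(spec.tumor_base * spec.fold)
        else:
            center = np.log2(spec.tumor_base)
        log2_expr.append(center + spec.sd_log2 * rng.standard_normal())
    log2_expr = np.asarray(log2_expr)

    ct_ref = spec.ct_ref_mean + spec.ct_ref_sd * rng.standard_normal(len(ids))
    ct_gene = ct_ref - log2_expr
    rows = []
    for sid, cr, cg in zip(ids, ct_ref, ct_gene):
        for _ in range(spec.replicates):
            rows.append({"sample_id": sid, "gene": spec.reference_gene,
                         "ct": cr + spec.replicate_sd * rng.standard_normal()})
            rows.append({"sample_id": sid, "gene": spec.gene,
                         "ct": cg + spec.replicate_sd * rng.standard_normal()})
    ct_table = pd.DataFrame(rows, columns=["sample_id", "gene", "ct"])
    truth = pd.DataFrame({"sample_id": ids, "role": roles,
                          "expression": 2.0 ** log2_expr})
    return ct_table, truth
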
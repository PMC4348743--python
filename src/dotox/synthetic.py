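"""Synthetic Diversity Outbred (DO) population generator with known ground truth.

Every downstream stage of the pipeline — diplotype reconstruction, kinship,
genome scans, heritability, dominance testing and benchmark-concentration
modeling — is exercised against data produced here, so the generator carries
the study conditions as its defaults:

* 8 founder strains, one of which (founder ``F``, CAST-like) carries private
  alleles across a focal interval on chromosome 10;
* mosaic genomes at outbreeding generation 7-8, with breakpoint density
  ``K_TRANSITION * generation`` per Mb per haplotype (see below);
* exposure groups at 0 / 1 / 10 / 100 ppm, balanced;
* log-normal micronucleated-reticulocyte (MN-RET) rates per 1,000 cells whose
  median follows the saturating exponential dose-response
  ``mu(X) = a * (c - (c - 1) * exp(-b * X))``;
* a dominant protective QTL sized to a target variance fraction at the top
  concentration, plus a polygenic term giving pre-exposure heritability 0.65.

Map-distance convention: positions are in Mb and the per-generation expected
recombination density is ``K_TRANSITION = 0.00125`` breakpoints per Mb per
haplotype per generation, i.e. about one breakpoint per 100 Mb per haplotype
in a generation-8 animal.  The HMM uses the same constant, so simulator and
reconstruction share one transition model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    CALL_SYMBOLS,
    FOUNDER_IDS,
    N_FOUNDERS,
    DiplotypeMosaic,
    FounderGenomes,
    HaplotypeDosage,
    TrueQtlSpec,
)

#: breakpoints per Mb per haplotype per generation of outbreeding
K_TRANSITION = 0.00125

#: default exponential dose-response parameters (a per-1000, b per ppm, c ratio)
DEFAULT_EXP_PARAMS = (2.5, 0.018, 6.0)

#: default residual log-scale SD of MN-RET rates (from a 2x control CI of ~2)
DEFAULT_SIGMA_LOG = 0.35

DEFAULT_DOSES = (0.0, 1.0, 10.0, 100.0)


def simulate_founder_genomes(
    n_chromosomes: int = 10,
    markers_per_chromosome: int = 30,
    private_interval: tuple[int, float, float] = (10, 28.0, 36.0),
    seed: int = 0,
    chromosome_length_mb: float = 90.0,
    private_founder: str = "F",
    maf_informative: float = 0.5,
) -> FounderGenomes:
    """Simulate biallelic founder alleles on an abstract, evenly spaced map.

    Outside the private interval each founder draws allele 1 independently
    with probability ``maf_informative`` (partially informative markers, as on
    a genotyping array).  Inside the private interval the private founder
    carries allele 1 and the other seven carry allele 0 at every marker, so
    the focal founder is the minor singleton throughout.
    """
    if markers_per_chromosome < 10:
        raise ValueError("markers_per_chromosome must be >= 10")
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    chrom, start, end = private_interval
    if not (1 <= chrom <= n_chromosomes):
        raise ValueError(
            f"private interval chromosome {chrom} outside 1..{n_chromosomes}"
        )
    if not (0 <= start < end <= chromosome_length_mb):
        raise ValueError(
            f"private interval ({start}, {end}) outside (0, {chromosome_length_mb}]"
        )

    rng = np.random.default_rng(seed)
    positions = np.linspace(3.0, chromosome_length_mb, markers_per_chromosome)
    rows = []
    for c in range(1, n_chromosomes + 1):
        for j, p in enumerate(positions):
            rows.append((f"m{c:02d}_{j + 1:03d}", c, float(p)))
    marker_map = pd.DataFrame(rows, columns=["marker", "chr", "pos_Mb"])

    alleles = (
        rng.random((len(marker_map), N_FOUNDERS)) < maf_informative
    ).astype(np.int8)
    f_idx = FOUNDER_IDS.index(private_founder)
    in_interval = (
        (marker_map["chr"] == chrom)
        & (marker_map["pos_Mb"] >= start)
        & (marker_map["pos_Mb"] <= end)
    ).to_numpy()
    alleles[in_interval, :] = 0
    alleles[in_interval, f_idx] = 1

    return FounderGenomes(
        founder_ids=FOUNDER_IDS,
        alleles=alleles,
        marker_map=marker_map,
        private_founder=private_founder,
        private_interval=private_interval,
    )


def _simulate_haplotype(length_mb: float, rate_per_mb: float, rng) -> list:
    """One haplotype as segments (start, end, founder).

    Switch events are a Poisson process with the given rate; at each event the
    new founder is uniform over all 8 (so a fraction 1/8 of events are
    invisible), which makes the marginal transition over any gap exactly
    ``(1 - r) I + (r / 8) J`` with ``r = 1 - exp(-rate * gap)`` — the same
    kernel the HMM uses, and consistent under composition.  Same-founder
    neighbours are merged, so segments record visible breakpoints only.
    """
    n_events = rng.poisson(rate_per_mb * length_mb)
    cuts = np.sort(rng.uniform(0.0, length_mb, size=n_events))
    bounds = np.concatenate([[0.0], cuts, [length_mb]])
    founders = [FOUNDER_IDS[rng.integers(N_FOUNDERS)] for _ in range(n_events + 1)]
    segments: list = []
    for i, f in enumerate(founders):
        if segments and segments[-1][2] == f:
            segments[-1] = (segments[-1][0], float(bounds[i + 1]), f)
        else:
            segments.append((float(bounds[i]), float(bounds[i + 1]), f))
    return segments


def simulate_do_population(
    founders: FounderGenomes,
    n_mice: int,
    generation: int = 8,
    seed: int = 0,
) -> list[DiplotypeMosaic]:
    """Simulate mosaic genomes for ``n_mice`` outbred animals.

    Expected breakpoints per haplotype per chromosome =
    ``K_TRANSITION * generation * length_Mb``; founder labels are uniform at
    stationarity.
    """
    if generation < 1:
        raise ValueError("generation must be >= 1")
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    rng = np.random.default_rng(seed)
    rate = K_TRANSITION * generation
    lengths = {
        c: float(founders.marker_map.loc[founders.marker_map["chr"] == c, "pos_Mb"].max())
        for c in founders.chromosomes
    }
    mosaics = []
    for i in range(n_mice):
        haps = {
            c: (
                _simulate_haplotype(lengths[c], rate, rng),
                _simulate_haplotype(lengths[c], rate, rng),
            )
            for c in founders.chromosomes
        }
        mosaics.append(
            DiplotypeMosaic(mouse_id=f"DO-{i + 1:04d}", generation=generation, haplotypes=haps)
        )
    return mosaics


def true_dosages(
    mosaics: list[DiplotypeMosaic], founders: FounderGenomes
) -> HaplotypeDosage:
    """Ground-truth founder dosages (integer 0/1/2 per founder) at every marker."""
    m = founders.marker_map
    arr = np.zeros((len(mosaics), len(m), N_FOUNDERS))
    findex = {f: k for k, f in enumerate(FOUNDER_IDS)}
    chroms = m["chr"].to_numpy()
    pos_all = m["pos_Mb"].to_numpy(float)
    for chrom in founders.chromosomes:
        idx = np.flatnonzero(chroms == chrom)
        pos = pos_all[idx]
        for i, mosaic in enumerate(mosaics):
            for hap in mosaic.haplotypes[chrom]:
                ends = np.array([seg[1] for seg in hap])
                fidx = np.array([findex[seg[2]] for seg in hap])
                seg_of = np.minimum(
                    np.searchsorted(ends, pos, side="left"), len(hap) - 1
                )
                np.add.at(arr[i], (idx, fidx[seg_of]), 1)
    out = HaplotypeDosage([mo.mouse_id for mo in mosaics], m, arr)
    out.validate()
    return out


def genotype_from_mosaic(
    mosaics: list[DiplotypeMosaic],
    founders: FounderGenomes,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    missing_rate_sd: float = 0.0,
) -> pd.DataFrame:
    """Biallelic genotype calls (markers x mice, values A/H/B/N).

    The call is the allele-1 copy number of the two underlying founder
    haplotypes (0 -> A, 1 -> H, 2 -> B).  With probability ``error_rate`` the
    call is replaced by one of the two wrong symbols uniformly; with
    probability ``missing_rate`` it is set to N (missingness is applied last).
    A positive ``missing_rate_sd`` gives each sample its own missingness
    (Gaussian around ``missing_rate``, truncated to [0, 0.49]), emulating
    array batches in which a few samples fall below the QC call-rate bar.
    """
    for name, rate in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not (0 <= rate < 0.5):
            raise ValueError(f"{name} must be in [0, 0.5), got {rate}")
    rng = np.random.default_rng(seed)
    dos = true_dosages(mosaics, founders).dosages  # (n, m, 8)
    counts = np.einsum("nmf,mf->nm", dos, founders.alleles).round().astype(int)  # 0/1/2

    if error_rate > 0:
        flip = rng.random(counts.shape) < error_rate
        # replace with one of the two other codes uniformly
        shift = 1 + rng.integers(2, size=counts.shape)
        counts = np.where(flip, (counts + shift) % 3, counts)
    symbols = np.array(["A", "H", "B"], dtype=object)
    calls = symbols[counts.T]  # (m, n)
    if missing_rate > 0 or missing_rate_sd > 0:
        per_mouse = np.clip(
            rng.normal(missing_rate, missing_rate_sd, size=calls.shape[1]),
            0.0,
            0.49,
        )
        miss = rng.random(calls.shape) < per_mouse[None, :]
        calls = np.where(miss, "N", calls)
    return pd.DataFrame(
        calls,
        index=founders.marker_map["marker"].to_numpy(),
        columns=[mo.mouse_id for mo in mosaics],
    )


def eval_dose_response(a: float, b: float, c: float, X) -> np.ndarray:
    """Median response mu(X) = a * (c - (c - 1) * exp(-b * X)). Local copy to
    keep the generator importable without the fitting module."""
    X = np.asarray(X, dtype=float)
    return a * (c - (c - 1.0) * np.exp(-b * X))


def assign_exposures(
    mouse_ids: list, doses=DEFAULT_DOSES, seed: int = 0
) -> pd.Series:
    """Balanced randomized exposure assignment (groups equal up to remainder)."""
    rng = np.random.default_rng(seed)
    n = len(mouse_ids)
    reps = int(np.ceil(n / len(doses)))
    pool = np.tile(np.asarray(doses, float), reps)[:n]
    rng.shuffle(pool)
    return pd.Series(pool, index=list(mouse_ids), name="exposure_ppm")


def _kinship_from_true(dosages: np.ndarray) -> np.ndarray:
    n, m, _ = dosages.shape
    p = (dosages / 2.0).reshape(n, -1)
    return (p @ p.T) / m


def qtl_effect_for_variance(g: np.ndarray, var_frac: float, other_var: float) -> float:
    """Effect size beta such that Var(beta*g) / (Var(beta*g) + other_var) = var_frac."""
    vg = float(np.var(g))
    if vg <= 0:
        raise ValueError("QTL coding has zero variance; cannot size effect")
    return float(np.sqrt(var_frac / (1.0 - var_frac) * other_var / vg))


def simulate_phenotypes(
    mosaics: list[DiplotypeMosaic],
    founders: FounderGenomes,
    qtl: TrueQtlSpec | None,
    exposure_assignment: pd.Series,
    exp_params: tuple[float, float, float] = DEFAULT_EXP_PARAMS,
    h2_target: float = 0.65,
    sigma_log: float = DEFAULT_SIGMA_LOG,
    seed: int = 0,
    cohorts: pd.Series | None = None,
) -> pd.DataFrame:
    """Forward-simulate the phenotype table for one study.

    For each mouse, on the natural-log scale::

        log(pre_pb)  = log(a)      + u + e_pre
        log(post_*)  = log(mu(X))  + beta * g * s(X) + u + e_post

    where ``u ~ MVN(0, sigma_g2 * K_true)`` is the polygenic term on the
    ground-truth dosage kinship, ``e`` are iid Gaussian, and variance
    components are scaled so Var(u) / (Var(u) + Var(e)) = ``h2_target`` with
    Var(u) + Var(e) = sigma_log**2.  ``g`` is the dominant (or additive)
    coding of the focal-founder dosage at the QTL marker and
    ``s(X) = (1 - exp(-bX)) / (1 - exp(-b*Xmax))`` scales the QTL effect with
    the induced-damage fraction, so the planted effect is absent before
    exposure and has full size at the top concentration.  Rates are reported
    per 1,000 cells.
    """
    a, b, c = exp_params
    if not (a > 0 and b > 0 and c > 1):
        raise ValueError("exp_params require a>0, b>0, c>1")
    if not (0 <= h2_target < 1):
        raise ValueError("h2_target must be in [0, 1)")
    mouse_ids = [mo.mouse_id for mo in mosaics]
    unknown = [m for m in exposure_assignment.index if m not in set(mouse_ids)]
    if unknown:
        raise KeyError(f"exposure assignment references unknown mice: {unknown[:5]}")
    if set(exposure_assignment.index) != set(mouse_ids):
        raise KeyError("exposure assignment must cover every simulated mouse")

    rng = np.random.default_rng(seed)
    n = len(mosaics)
    X = exposure_assignment.loc[mouse_ids].to_numpy(float)
    xmax = float(X.max())

    truth = true_dosages(mosaics, founders)
    sigma_g2 = h2_target * sigma_log**2
    sigma_e2 = (1.0 - h2_target) * sigma_log**2
    if sigma_g2 > 0:
        K = _kinship_from_true(truth.dosages)
        K = K / np.mean(np.diag(K))  # unit mean diagonal so Var(u_i) ~= sigma_g2
        L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        u = np.sqrt(sigma_g2) * (L @ rng.standard_normal(n))
    else:
        u = np.zeros(n)

    g = np.zeros(n)
    beta = 0.0
    if qtl is not None:
        d_focal = truth.founder_dosage_at(
            qtl.chromosome, qtl.position_mb, qtl.focal_founder
        )
        if qtl.mode == "dominant":
            g = (d_focal >= 1).astype(float)
        else:
            g = d_focal / 2.0
        if qtl.effect_size is not None:
            beta = float(qtl.effect_size)
        else:
            beta = qtl_effect_for_variance(
                g[X == xmax] if np.any(X == xmax) else g, qtl.var_frac, sigma_log**2
            )
        if qtl.protective:
            beta = -beta

    if xmax > 0:
        s = (1.0 - np.exp(-b * X)) / (1.0 - np.exp(-b * xmax))
    else:
        s = np.zeros(n)
    mu = eval_dose_response(a, b, c, X)

    sd_e = np.sqrt(sigma_e2)
    pre = np.exp(np.log(a) + u + sd_e * rng.standard_normal(n))
    post_pb = np.exp(np.log(mu) + beta * g * s + u + sd_e * rng.standard_normal(n))
    post_bm = np.exp(np.log(mu) + beta * g * s + u + sd_e * rng.standard_normal(n))
    # %RET around ~3% with mild log-normal spread; not analyzed downstream
    pct_ret = np.exp(np.log(3.0) + 0.2 * rng.standard_normal(n))

    if cohorts is None:
        cohort = np.where(np.arange(n) < n // 2, 1, 2)
    else:
        cohort = cohorts.loc[mouse_ids].to_numpy(int)

    table = pd.DataFrame(
        {
            "mouse_id": mouse_ids,
            "cohort": cohort,
            "exposure_ppm": X,
            "pre_pb_mnret": pre,
            "post_pb_mnret": post_pb,
            "post_bm_mnret": post_bm,
            "pct_ret": pct_ret,
        }
    )
    table.attrs["truth"] = {
        "exp_params": {"a": a, "b": b, "c": c},
        "h2_target": h2_target,
        "sigma_log": sigma_log,
        "sigma_g2": sigma_g2,
        "sigma_e2": sigma_e2,
        "qtl": qtl.to_dict() if qtl is not None else None,
        "qtl_beta": beta,
        "seed": seed,
    }
    return table


def simulate_dose_response(
    doses=DEFAULT_DOSES,
    n_per_group: int = 75,
    a: float = DEFAULT_EXP_PARAMS[0],
    b: float = DEFAULT_EXP_PARAMS[1],
    c: float = DEFAULT_EXP_PARAMS[2],
    sigma_log: float = DEFAULT_SIGMA_LOG,
    seed: int = 0,
) -> pd.DataFrame:
    """Individual-animal log-normal dose-response records (dose_ppm, response).

    A lean generator for the benchmark-concentration engine: responses are
    log-normal with median mu(X) and constant log-scale SD, with no genetic
    structure.  Used for parameter-recovery and coverage simulations.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        mu = float(eval_dose_response(a, b, c, d))
        y = np.exp(np.log(mu) + sigma_log * rng.standard_normal(n_per_group))
        rows.append(pd.DataFrame({"dose_ppm": d, "response": y}))
    return pd.concat(rows, ignore_index=True)
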
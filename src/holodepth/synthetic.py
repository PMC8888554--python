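"""Synthetic holobiont data with planted, recoverable structure.

The generators emulate the study design every downstream stage expects:
samples spread along a bathyal depth gradient spanning two water masses,
16S ASV count tables whose composition drifts log-linearly with depth,
near-identical ASV sequence pairs responding to depth in opposite
directions (candidate water-mass ecotypes), and untargeted LC-MS feature
tables with void-eluting features, adduct groups sharing a ``pc_group``,
interspersed pooled-QC injections with controlled technical variability,
and depth-trending compound signals.

Every planted effect is recorded in a :class:`SyntheticTruth` ledger so
recovery, calibration and null behaviour of the analysis stages can be
asserted against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import spawn_rng
from .tables import AsvTable, MetaboFeatureTable, SequenceSet, water_mass_label

#: Depth range (m) of the emulated survey.
DEFAULT_DEPTH_RANGE = (244.0, 1476.0)

#: Mean observed per-sample richness targeted by the two community profiles
#: (rich high-microbial-abundance vs poor low-microbial-abundance hosts).
HMA_RICHNESS_MEAN = 190
LMA_RICHNESS_MEAN = 30

VOID_RT_MAX_S = 40.0


@dataclass
class SyntheticTruth:
    """Ledger of every effect planted by a generator.

    responsive: variable id -> signed log-linear slope per km of depth.
    sister_pairs: (id_a, id_b, identity, slope_a, slope_b) tuples.
    planted_associations: (id_a, id_b, basis correlation) tuples.
    qc_cv_targets: feature id -> intended QC coefficient of variation.
    void_ids: features planted with retention time < 40 s.
    high_cv_ids: features planted with QC CV above the cleaning threshold.
    pc_representatives: pc_group -> feature with maximal cumulative signal.
    """

    responsive: dict[str, float] = field(default_factory=dict)
    sister_pairs: list[tuple[str, str, float, float, float]] = field(default_factory=list)
    planted_associations: list[tuple[str, str, float]] = field(default_factory=list)
    qc_cv_targets: dict[str, float] = field(default_factory=dict)
    void_ids: list[str] = field(default_factory=list)
    high_cv_ids: list[str] = field(default_factory=list)
    pc_representatives: dict[int, str] = field(default_factory=dict)

    @property
    def responsive_ids(self) -> set[str]:
        return set(self.responsive)

    def validate_against(self, *, asv_table: AsvTable | None = None,
                         sequences: SequenceSet | None = None,
                         feature_table: MetaboFeatureTable | None = None) -> None:
        """Check that every planted id resolves against the emitted tables."""
        known: set[str] = set()
        if asv_table is not None:
            known |= set(asv_table.asv_ids)
        if feature_table is not None:
            known |= set(feature_table.feature_ids)
        planted = set(self.responsive) | set(self.qc_cv_targets)
        planted |= set(self.void_ids) | set(self.high_cv_ids)
        for a, b, *_ in self.sister_pairs:
            planted |= {a, b}
        for a, b, _ in self.planted_associations:
            planted |= {a, b}
        planted |= set(self.pc_representatives.values())
        unresolved = planted - known
        if unresolved:
            raise ValueError(f"planted ids missing from tables: {sorted(unresolved)[:5]}")
        if sequences is not None:
            for a, b, identity, sa, sb in self.sister_pairs:
                if a not in sequences.sequences or b not in sequences.sequences:
                    raise ValueError(f"sister pair ({a},{b}) missing sequences")
                if sa * sb >= 0:
                    raise ValueError(f"sister pair ({a},{b}) slopes do not oppose")


def simulate_metadata(
    n_samples: int,
    depth_range: tuple[float, float] = DEFAULT_DEPTH_RANGE,
    collinearity: float = 0.9,
    seed: int = 0,
    species: str = "G_barretti_like",
) -> pd.DataFrame:
    """Simulate a sample-metadata frame along the depth gradient.

    Depths are uniform over ``depth_range``. Temperature and salinity are
    linear in depth plus Gaussian noise scaled so the population
    correlation with depth equals ``collinearity`` (1 = deterministic,
    0 = independent), reproducing the confounding between depth and the
    hydrographic variables a real transect shows.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    lo, hi = depth_range
    if not hi > lo:
        raise ValueError("depth_range must be non-degenerate")
    if not 0.0 <= collinearity <= 1.0:
        raise ValueError("collinearity must be in [0, 1]")
    rng = spawn_rng(seed, "metadata", species)

    depth = rng.uniform(lo, hi, n_samples)
    mid = 0.5 * (lo + hi)
    sd_depth = (hi - lo) / np.sqrt(12.0)

    def _collinear(slope: float, intercept: float, noise_floor: float) -> np.ndarray:
        signal_sd = abs(slope) * sd_depth
        if collinearity == 0.0:
            return intercept + rng.normal(0.0, max(signal_sd, noise_floor), n_samples)
        noise_sd = signal_sd * np.sqrt(1.0 / collinearity**2 - 1.0)
        return intercept + slope * (depth - mid) + rng.normal(0.0, noise_sd, n_samples)

    # Hydrography of the emulated transect: warm/salty upper water mass over
    # a colder, fresher deep one (~4.5 degC / 34.93 psu near 600 m vs
    # ~3.7 degC / 34.89 psu near 1200 m).
    temperature = _collinear(-0.8 / 600.0, 4.1, 0.05)
    salinity = _collinear(-0.04 / 600.0, 34.91, 0.005)

    meta = pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(n_samples)],
            "species": species,
            "depth": depth,
            "latitude": rng.uniform(60.0, 64.0, n_samples),
            "longitude": rng.uniform(-61.0, -57.0, n_samples),
            "temperature": temperature,
            "salinity": salinity,
            "year": rng.integers(2011, 2016, n_samples),
            "water_mass": water_mass_label(depth),
        }
    )
    return meta


def _random_sequences(n: int, length: int, rng: np.random.Generator) -> list[str]:
    alphabet = np.array(list("ACGT"))
    return ["".join(alphabet[rng.integers(0, 4, length)]) for _ in range(n)]


def _mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Substitute exactly ``n_subs`` positions (chosen without replacement)."""
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_asv_table(
    metadata: pd.DataFrame,
    profile: str = "HMA",
    n_asvs: int = 300,
    frac_responsive: float = 0.3,
    n_sister_pairs: int = 0,
    effect_size: float = 2.0,
    identity_target: float = 0.97,
    seed: int = 0,
    sequence_length: int = 140,
    n_assoc_pairs: int = 0,
    assoc_strength: float = 0.8,
    library_size_mean: float = 2e4,
    library_size_sigma: float = 0.25,
    sample_noise_sd: float = 0.1,
    assoc_noise_sd: float = 1.0,
    baseline_sigma: float | None = None,
    exact_null: bool = False,
) -> tuple[AsvTable, SequenceSet, SyntheticTruth]:
    """Simulate a depth-structured ASV count table with planted effects.

    Counts follow a Dirichlet-multinomial: each ASV has a log-normal
    baseline concentration; responsive ASVs add ``slope * depth_km`` to
    their log-concentration (slope magnitude ``effect_size`` per km, signs
    balanced). The "HMA" profile makes nearly all ASVs detectable per
    sample (rich communities); "LMA" restricts the community to a small
    core so per-sample richness lands near the poor-host mean.

    ``n_sister_pairs`` near-identical sequence pairs (differing at exactly
    ``floor((1-identity_target)*L)`` positions) are planted on responsive
    ASVs with opposing slopes. ``n_assoc_pairs`` pairs receive correlated
    log-abundance fluctuations of basis correlation ``assoc_strength``
    (for co-occurrence network recovery).
    """
    if not 0.0 < identity_target <= 1.0:
        raise ValueError("identity_target must be in (0, 1]")
    if n_asvs < 2 * n_sister_pairs:
        raise ValueError("n_asvs must be >= 2 * n_sister_pairs")
    if not 0.0 <= frac_responsive <= 1.0:
        raise ValueError("frac_responsive must be in [0, 1]")
    if profile not in ("HMA", "LMA"):
        raise ValueError("profile must be 'HMA' or 'LMA'")
    rng = spawn_rng(seed, "asv_table", profile)

    n_samples = len(metadata)
    depth_km = metadata["depth"].to_numpy(dtype=float) / 1000.0
    asv_ids = [f"ASV{i:04d}" for i in range(n_asvs)]

    # Community structure: a detectable "core" whose members are present in
    # essentially every sample, plus effectively absent non-core ASVs. Core
    # size and baseline spread are calibrated so mean observed richness
    # lands near 190 (HMA) / 30 (LMA); ``theta`` sets the total Dirichlet
    # concentration (mild multinomial overdispersion).
    if profile == "HMA":
        n_core = min(int(round(HMA_RICHNESS_MEAN * 1.03)), n_asvs)
        theta = 2000.0
    else:
        n_core = min(max(int(round(LMA_RICHNESS_MEAN * 1.06)), 2), n_asvs)
        theta = 2000.0
    base_sigma = 0.8 if baseline_sigma is None else baseline_sigma
    baseline = rng.normal(0.0, base_sigma, n_asvs)
    core = np.zeros(n_asvs, dtype=bool)
    core[rng.choice(n_asvs, size=n_core, replace=False)] = True
    baseline[~core] = -12.0  # effectively absent outside the core

    truth = SyntheticTruth()

    # Depth-responsive ASVs (chosen inside the core so they are observable),
    # balanced between increasing and decreasing.
    n_resp = int(round(frac_responsive * n_asvs))
    core_idx = np.flatnonzero(core)
    n_resp = min(n_resp, core_idx.size)
    resp_idx = rng.choice(core_idx, size=n_resp, replace=False)
    slopes = np.zeros(n_asvs)
    signs = np.ones(n_resp)
    signs[: n_resp // 2] = -1.0
    rng.shuffle(signs)
    slopes[resp_idx] = signs * effect_size
    for i in resp_idx:
        truth.responsive[asv_ids[i]] = float(slopes[i])

    # Sister pairs: opposing-slope responsive ASVs, near-identical sequences.
    seqs = _random_sequences(n_asvs, sequence_length, rng)
    n_subs = int(np.floor((1.0 - identity_target) * sequence_length))
    pos_idx = [i for i in resp_idx if slopes[i] > 0]
    neg_idx = [i for i in resp_idx if slopes[i] < 0]
    if n_sister_pairs > min(len(pos_idx), len(neg_idx)):
        raise ValueError(
            "not enough opposing responsive ASVs for the requested sister pairs; "
            "raise frac_responsive"
        )
    for k in range(n_sister_pairs):
        a, b = pos_idx[k], neg_idx[k]
        seqs[b] = _mutate(seqs[a], n_subs, rng)
        identity = (sequence_length - n_subs) / sequence_length
        ia, ib = sorted([asv_ids[a], asv_ids[b]])
        sa = truth.responsive[ia]
        sb = truth.responsive[ib]
        truth.sister_pairs.append((ia, ib, identity, sa, sb))

    # Correlated log-abundance fluctuations for planted associations, on
    # non-responsive core ASVs so the association is not a depth echo. The
    # associated pairs fluctuate on their own (larger) scale so the planted
    # basis correlation is not washed out by counting noise.
    noise = rng.normal(0.0, sample_noise_sd, (n_samples, n_asvs))
    free = [i for i in core_idx if slopes[i] == 0.0]
    rng.shuffle(free)
    if n_assoc_pairs * 2 > len(free):
        raise ValueError("not enough non-responsive core ASVs for planted associations")
    if n_assoc_pairs > 0:
        if exact_null and n_samples <= n_asvs + n_assoc_pairs:
            raise ValueError(
                "exact_null needs n_samples > n_asvs + n_assoc_pairs "
                "(joint orthogonalisation)"
            )
        if exact_null:
            # Realised-sample ground truth: shared factors and every ASV's
            # individual fluctuation are drawn jointly orthogonal, so
            # unplanted pairs have exactly zero noise correlation in this
            # sample and planted pairs exactly the requested basis
            # correlation (up to compositional closure and counting noise).
            raw = rng.normal(0.0, 1.0, (n_samples, n_assoc_pairs + n_asvs))
            q, _ = np.linalg.qr(raw - raw.mean(axis=0))
            q *= np.sqrt(n_samples)
            factors = q[:, :n_assoc_pairs] * assoc_noise_sd
            noise = q[:, n_assoc_pairs:] * sample_noise_sd
        else:
            # Shared factors orthogonalised across pairs so distinct pairs
            # are uncorrelated by construction, not just in expectation.
            raw = rng.normal(0.0, 1.0, (n_samples, n_assoc_pairs))
            q, _ = np.linalg.qr(raw - raw.mean(axis=0))
            factors = q * np.sqrt(n_samples) * assoc_noise_sd
        for k in range(n_assoc_pairs):
            a, b = free[2 * k], free[2 * k + 1]
            r = assoc_strength
            for col in (a, b):
                if exact_null:  # reuse the (orthogonal) column as own noise
                    indiv = noise[:, col] * (assoc_noise_sd / sample_noise_sd)
                else:
                    indiv = rng.normal(0.0, assoc_noise_sd, n_samples)
                noise[:, col] = np.sqrt(r) * factors[:, k] + np.sqrt(1 - r) * indiv
            ia, ib = sorted([asv_ids[a], asv_ids[b]])
            truth.planted_associations.append((ia, ib, float(assoc_strength)))

    log_conc = baseline[None, :] + np.outer(depth_km, slopes) + noise
    # Stabilise the per-sample scale so depth effects act on composition,
    # not on total concentration.
    log_conc -= log_conc.max(axis=1, keepdims=True)
    conc = np.exp(log_conc)
    conc = theta * conc / conc.sum(axis=1, keepdims=True)

    library = rng.lognormal(np.log(library_size_mean), library_size_sigma, n_samples)
    counts = np.empty((n_samples, n_asvs), dtype=np.int64)
    for s in range(n_samples):
        p = rng.dirichlet(np.maximum(conc[s], 1e-12))
        counts[s] = rng.multinomial(int(library[s]), p)

    table = AsvTable(
        pd.DataFrame(counts, index=list(metadata["sample_id"]), columns=asv_ids),
        kind="counts",
    )
    seqset = SequenceSet(dict(zip(asv_ids, seqs)))
    truth.validate_against(asv_table=table, sequences=seqset)
    return table, seqset, truth


def simulate_metabolome(
    metadata: pd.DataFrame,
    n_features: int = 200,
    n_pc_groups: int = 40,
    frac_void: float = 0.1,
    frac_high_cv: float = 0.1,
    frac_responsive: float = 0.2,
    n_qc: int = 8,
    seed: int = 0,
    mode: tuple[str, str] = ("HILIC", "positive"),
    effect_size: float = 1.5,
    high_cv_target: float = 0.8,
    low_cv_target: float = 0.08,
    sample_scaling_sd: float = 0.8,
) -> tuple[MetaboFeatureTable, SyntheticTruth]:
    """Simulate an annotated LC-MS feature table with planted structure.

    Features are grouped into ``n_pc_groups`` adduct clusters sharing one
    latent compound signal per sample (members proportional up to
    log-normal noise). Exactly ``ceil(frac_void * n_features)`` features
    elute in the void (retention time < 40 s). A planted subset gets
    multiplicative QC noise with coefficient of variation
    ``high_cv_target`` (> 0.30); the rest ``low_cv_target``. One feature
    per pc_group carries the molecular-ion annotation for the acquisition
    polarity ("[M+H]+" or "[M-H]-"); other members are "adduct",
    "isotope" or unannotated. Responsive compounds trend log-linearly
    with depth at ``effect_size`` per km (signs balanced).
    """
    if n_qc < 2:
        raise ValueError("n_qc must be >= 2 (a CV needs at least two QC injections)")
    chrom, polarity = mode
    rng = spawn_rng(seed, "metabolome", chrom, polarity)

    n_samples = len(metadata)
    depth_km = metadata["depth"].to_numpy(dtype=float) / 1000.0
    feature_ids = [f"F{i:04d}" for i in range(n_features)]
    sample_cols = list(metadata["sample_id"])
    qc_cols = [f"QC{i:02d}" for i in range(n_qc)]

    # Assign features to pc_groups (every group non-empty).
    groups = np.concatenate(
        [np.arange(n_pc_groups), rng.integers(0, n_pc_groups, n_features - n_pc_groups)]
    )[:n_features]
    rng.shuffle(groups)

    truth = SyntheticTruth()

    # Latent compound signal per pc_group; a subset trends with depth.
    n_resp = int(round(frac_responsive * n_features))
    resp_features = rng.choice(n_features, size=n_resp, replace=False)
    resp_groups = np.unique(groups[resp_features])
    group_slope = np.zeros(n_pc_groups)
    signs = np.where(np.arange(resp_groups.size) % 2 == 0, 1.0, -1.0)
    rng.shuffle(signs)
    group_slope[resp_groups] = signs * effect_size
    group_base = rng.normal(14.0, 1.0, n_pc_groups)  # log-intensity scale
    compound_log = group_base[None, :] + np.outer(depth_km, group_slope)
    compound_log += rng.normal(0.0, 0.3, (n_samples, n_pc_groups))

    # Feature-level proportionality within a group (adduct yield) + noise,
    # plus a global per-sample intensity factor (extract concentration /
    # injection variability), which dominates the between-feature
    # covariance of real LC-MS tables.
    feat_offset = rng.normal(-0.5, 0.5, n_features)
    sample_factor = rng.normal(0.0, sample_scaling_sd, n_samples)
    log_int = compound_log[:, groups] + feat_offset[None, :]
    log_int += sample_factor[:, None]
    log_int += rng.normal(0.0, 0.1, (n_samples, n_features))
    intensities = np.exp(log_int).T  # features x samples

    # Responsive features = members of responsive groups (their shared
    # compound trends); record each with its group slope.
    for j in range(n_features):
        s = group_slope[groups[j]]
        if s != 0.0:
            truth.responsive[feature_ids[j]] = float(s)

    # Retention times: exactly ceil(frac_void * n) void features.
    n_void = int(np.ceil(frac_void * n_features))
    rt = rng.uniform(45.0, 600.0, n_features)
    void_idx = rng.choice(n_features, size=n_void, replace=False)
    rt[void_idx] = rng.uniform(5.0, VOID_RT_MAX_S - 1.0, n_void)
    truth.void_ids = [feature_ids[j] for j in void_idx]

    # QC injections: pooled-sample level with feature-specific technical CV.
    n_high = int(round(frac_high_cv * n_features))
    high_idx = rng.choice(n_features, size=n_high, replace=False)
    cv = np.full(n_features, low_cv_target)
    cv[high_idx] = high_cv_target
    truth.high_cv_ids = [feature_ids[j] for j in high_idx]
    truth.qc_cv_targets = dict(zip(feature_ids, cv.tolist()))
    qc_level = intensities.mean(axis=1)
    # Log-normal multiplicative noise with the requested CV.
    sigma_qc = np.sqrt(np.log1p(cv**2))
    qc = qc_level[:, None] * np.exp(
        rng.normal(0.0, 1.0, (n_features, n_qc)) * sigma_qc[:, None]
        - 0.5 * sigma_qc[:, None] ** 2
    )

    # Annotations: the highest-yield member of a subset of groups is the
    # molecular ion; the rest are adducts/isotopes/unannotated.
    ion_label = "[M+H]+" if polarity == "positive" else "[M-H]-"
    annotation = np.array([""] * n_features, dtype=object)
    n_ion_groups = max(1, int(round(0.8 * n_pc_groups)))
    ion_groups = rng.choice(n_pc_groups, size=n_ion_groups, replace=False)
    for g in range(n_pc_groups):
        members = np.flatnonzero(groups == g)
        if members.size == 0:
            continue
        lead = members[np.argmax(feat_offset[members])]
        if g in ion_groups:
            annotation[lead] = ion_label
        others = [m for m in members if m != lead]
        for m in others:
            annotation[m] = rng.choice(["adduct", "isotope", ""])

    mz = rng.uniform(80.0, 1200.0, n_features)
    features = pd.DataFrame(
        {
            "retention_time": rt,
            "mz": mz,
            "annotation": annotation,
            "pc_group": groups.astype(int),
        },
        index=feature_ids,
    )
    intensity_df = pd.DataFrame(
        np.hstack([intensities, qc]),
        index=feature_ids,
        columns=sample_cols + qc_cols,
    )
    table = MetaboFeatureTable(intensity_df, features, qc_columns=qc_cols, mode=mode)

    # Maximal-cumulative-signal representative per pc_group, computed from
    # the emitted table with the same tie rule the pc_group filter uses.
    study = intensity_df[sample_cols]
    for g in sorted(set(groups.tolist())):
        members = features.index[features["pc_group"] == g]
        sums = study.loc[members].sum(axis=1)
        best = sums[sums == sums.max()].index.min()
        truth.pc_representatives[int(g)] = best

    truth.validate_against(feature_table=table)
    return table, truth
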
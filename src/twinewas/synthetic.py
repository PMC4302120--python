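"""Synthetic twin-methylation data generator.

Emulates a cohort of adult monozygotic twin pairs discordant for birth
weight, profiled on a methylation array: bimodal age structure (a young and
an old recruitment wave), right-skewed intra-pair birth-weight discordance,
shared-pair correlation in methylation, plate/well/array-position batch
structure, six-cell-type blood composition, technical replicates on one
pair, failing probes, and planted qualitative / quantitative /
age-dependent / sex-dependent intra-pair effects.  Every planted feature is
recorded in a :class:`TruthRecord` so downstream modules can be tested for
recovery.

The generative scale is the natural-log logit of the beta value, so planted
coefficients match the analysis model's odds-ratio interpretation
(``exp(coefficient)`` per covariate unit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .containers import MethylationMatrix, TwinCohort, ValidationError

__all__ = [
    "GeneratorConfig",
    "TruthRecord",
    "generate_cohort",
    "generate_methylation",
    "write_fixture",
    "DEFAULT_CELL_TYPES",
]

DEFAULT_CELL_TYPES = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran")

# named RNG streams so that component draws do not depend on each other or
# on twin-role labels (required for the label-antisymmetry property)
_STREAMS = {
    "cohort": 0,
    "baseline": 1,
    "reference": 2,
    "compositions": 3,
    "pair_effects": 4,
    "batch": 5,
    "noise": 6,
    "probe_roles": 7,
    "detection_p": 8,
    "replicates": 9,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


class ConfigurationError(ValidationError):
    """Invalid generator configuration; the message names the field."""


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort and methylation matrix.

    Defaults reflect the emulated study: 150 pairs on a 450K-style array
    (desk-scale 20,000 probes), ages in two waves (30-37 and 57-74),
    discordance ``dbw%`` with median ~18% and support within (5, 48),
    arrays of 12 samples = 6 pairs, and whole-blood six-cell-type mixtures.
    """

    n_pairs: int = 150
    n_probes: int = 20_000
    seed: int = 0

    # planted effect structure (logit scale)
    frac_causal_alpha: float = 0.01
    frac_causal_dbw: float = 0.01
    frac_causal_age: float = 0.01
    frac_causal_sex: float = 0.0
    alpha_true: float = 0.2           # qualitative discordance: added to smaller twin
    beta_dbw_true: float = -0.02      # per percent discordance
    delta_age_true: float = 0.01      # per year of age
    gamma_sex_true: float = 0.1       # female pairs (indicator = 1)

    # variance components (logit scale)
    pair_sd: float = 0.5              # shared pair effect tau
    individual_sd: float = 0.25       # per-sample noise sigma
    batch_sd: float = 0.1             # plate/well/sentrix offsets
    replicate_sd: float = 0.05        # technical replicate noise
    bad_pair_sd: float = 1.5          # per-twin independent pair effect in bad pairs

    # baseline methylation: mixture of two peaks near beta 0.1 and 0.9
    baseline_peaks: tuple = (0.1, 0.9)
    baseline_sd: float = 0.5

    # cell composition
    n_cell_types: int = 6
    cell_types: tuple = DEFAULT_CELL_TYPES
    dirichlet_conc: tuple = (2.5, 5.0, 2.0, 2.0, 2.5, 16.0)
    n_reference_probes: int | None = None  # default: min(500, max(K, n_probes // 10))

    # QC structure
    n_bad_pairs: int = 3
    n_failing_probes: int = 14        # replicate-unstable probes
    n_high_missing_probes: int = 14   # probes failed by detection-p missingness
    sporadic_missing_rate: float = 5e-4
    n_replicates_per_twin: int = 4

    # cohort demography
    frac_old: float = 77 / 150
    age_young: tuple = (30, 37)
    age_old: tuple = (57, 74)
    male_pair_frac: float = 0.52
    bw_bigger_mean: float = 2760.0
    bw_bigger_sd: float = 480.0
    bw_range: tuple = (1100.0, 4625.0)
    dbw_beta_shape: tuple = (2.0, 4.0)
    dbw_range: tuple = (5.0, 48.0)
    ga_range: tuple = (33, 42)
    ga_missing_frac_old: float = 0.5
    reference_year: int = 2009        # recruitment year for age -> birth-year mapping

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise ConfigurationError("n_pairs must be >= 2")
        if self.n_probes < 1:
            raise ConfigurationError("n_probes must be >= 1")
        for name in ("frac_causal_alpha", "frac_causal_dbw", "frac_causal_age", "frac_causal_sex",
                     "frac_old", "male_pair_frac", "ga_missing_frac_old", "sporadic_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("pair_sd", "individual_sd", "batch_sd", "replicate_sd", "bad_pair_sd",
                     "baseline_sd", "bw_bigger_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_cell_types != len(self.dirichlet_conc) or self.n_cell_types != len(self.cell_types):
            raise ConfigurationError("n_cell_types must match dirichlet_conc and cell_types lengths")
        if any(c <= 0 for c in self.dirichlet_conc):
            raise ConfigurationError("dirichlet_conc entries must be positive")
        for name in ("n_bad_pairs", "n_failing_probes", "n_high_missing_probes", "n_replicates_per_twin"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_bad_pairs >= self.n_pairs:
            raise ConfigurationError("n_bad_pairs must be smaller than n_pairs")
        lo, hi = self.dbw_range
        if not (0 < lo < hi < 100):
            raise ConfigurationError("dbw_range must satisfy 0 < low < high < 100")


@dataclass
class TruthRecord:
    """Ground truth of a generated dataset, for recovery testing."""

    causal_alpha: dict      # probe id -> planted intercept effect
    causal_dbw: dict        # probe id -> per-percent slope
    causal_age: dict        # probe id -> per-year slope
    causal_sex: dict        # probe id -> female-pair effect
    compositions: pd.DataFrame  # samples x cell types, rows sum to 1
    reference: pd.DataFrame     # reference probes x cell types (beta scale)
    failing_probes: list        # replicate-unstable probe ids
    high_missing_probes: list   # probes planted to exceed the missingness cut
    bad_pairs: list             # pair ids with broken pair effect
    replicate_pair: str | None  # pair carrying the technical replicates

    def validate(self, probe_ids=None) -> None:
        w = self.compositions.to_numpy()
        if (w < 0).any():
            raise ValidationError("compositions must be non-negative")
        if not np.allclose(w.sum(axis=1), 1.0):
            raise ValidationError("compositions must sum to 1 per sample")
        if probe_ids is not None:
            known = set(probe_ids)
            for d in (self.causal_alpha, self.causal_dbw, self.causal_age, self.causal_sex):
                missing = set(d) - known
                if missing:
                    raise ValidationError(f"causal probes absent from matrix: {sorted(missing)[:5]}")

    def to_json(self, path) -> None:
        obj = {
            "causal_alpha": self.causal_alpha,
            "causal_dbw": self.causal_dbw,
            "causal_age": self.causal_age,
            "causal_sex": self.causal_sex,
            "compositions": {"index": self.compositions.index.tolist(),
                             "columns": self.compositions.columns.tolist(),
                             "values": self.compositions.to_numpy().tolist()},
            "reference": {"index": self.reference.index.tolist(),
                          "columns": self.reference.columns.tolist(),
                          "values": self.reference.to_numpy().tolist()},
            "failing_probes": self.failing_probes,
            "high_missing_probes": self.high_missing_probes,
            "bad_pairs": self.bad_pairs,
            "replicate_pair": self.replicate_pair,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        obj = json.loads(Path(path).read_text())
        comp = pd.DataFrame(obj["compositions"]["values"], index=obj["compositions"]["index"],
                            columns=obj["compositions"]["columns"])
        ref = pd.DataFrame(obj["reference"]["values"], index=obj["reference"]["index"],
                           columns=obj["reference"]["columns"])
        return cls(obj["causal_alpha"], obj["causal_dbw"], obj["causal_age"], obj["causal_sex"],
                   comp, ref, obj["failing_probes"], obj["high_missing_probes"],
                   obj["bad_pairs"], obj["replicate_pair"])


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

# gestational-age pmf over 33..42 weeks, median 39
_GA_PMF = np.array([0.02, 0.02, 0.03, 0.05, 0.08, 0.12, 0.25, 0.25, 0.13, 0.05])


def generate_cohort(config: GeneratorConfig) -> TwinCohort:
    """Draw a twin cohort with the configured demography.

    Pairs are laid out six to a plate (arrays of 12 samples), twins of a
    pair always sharing plate, well and sentrix position.  The first pair
    additionally carries ``n_replicates_per_twin`` technical replicates per
    twin (rows with ``is_replicate_of`` set).
    """
    config.validate()
    rng = _rng(config.seed, "cohort")
    n = config.n_pairs

    n_old = int(round(config.frac_old * n))
    old = np.zeros(n, dtype=bool)
    old[rng.permutation(n)[:n_old]] = True
    ages = np.where(
        old,
        rng.integers(config.age_old[0], config.age_old[1] + 1, size=n),
        rng.integers(config.age_young[0], config.age_young[1] + 1, size=n),
    )
    sexes = np.where(rng.random(n) < config.male_pair_frac, "male", "female")

    lo, hi = config.bw_range
    a = (lo - config.bw_bigger_mean) / config.bw_bigger_sd
    b = (hi - config.bw_bigger_mean) / config.bw_bigger_sd
    bw_big = truncnorm.rvs(a, b, loc=config.bw_bigger_mean, scale=config.bw_bigger_sd,
                           size=n, random_state=rng)
    dlo, dhi = config.dbw_range
    dbw = dlo + (dhi - dlo) * rng.beta(*config.dbw_beta_shape, size=n)
    bw_small = bw_big * (1.0 - dbw / 100.0)
    bw_big = np.round(bw_big)
    bw_small = np.round(bw_small)

    birth_year = config.reference_year - ages
    ga = rng.choice(np.arange(config.ga_range[0], config.ga_range[1] + 1), size=n, p=_GA_PMF)
    ga = ga.astype(float)
    pre1973 = birth_year < 1973
    ga_missing = pre1973 & (rng.random(n) < config.ga_missing_frac_old)
    ga[ga_missing] = np.nan

    # six pairs per array; well and slide-position cycles are out of phase so
    # the three batch factors are crossed rather than aliased
    plates = [f"P{i // 6 + 1:02d}" for i in range(n)]
    wells = [f"W{(i // 2) % 8 + 1}" for i in range(n)]
    sentrix = [f"R{i % 6 + 1:02d}C{(i // 6) % 2 + 1:02d}" for i in range(n)]

    rows = []
    for i in range(n):
        pid = f"pair{i + 1:03d}"
        common = dict(pair_id=pid, age=int(ages[i]), sex=sexes[i], birth_year=int(birth_year[i]),
                      gestational_age=ga[i], plate=plates[i], well=wells[i],
                      sentrix_position=sentrix[i], is_replicate_of=None)
        rows.append(dict(sample_id=f"{pid}_B", twin_role="bigger", birth_weight=bw_big[i], **common))
        rows.append(dict(sample_id=f"{pid}_S", twin_role="smaller", birth_weight=bw_small[i], **common))

    # technical replicates on the first pair
    if config.n_replicates_per_twin > 0:
        for base in (rows[0], rows[1]):
            for r in range(1, config.n_replicates_per_twin + 1):
                rep = dict(base)
                rep["sample_id"] = f"{base['sample_id']}_rep{r}"
                rep["is_replicate_of"] = base["sample_id"]
                rows.append(rep)

    df = pd.DataFrame(rows)
    df["is_replicate_of"] = df["is_replicate_of"].astype(object)
    return TwinCohort(df)


# ---------------------------------------------------------------------------
# methylation generation
# ---------------------------------------------------------------------------

def _resolve_n_reference(config: GeneratorConfig) -> int:
    if config.n_reference_probes is not None:
        return config.n_reference_probes
    return min(500, max(config.n_cell_types, config.n_probes // 10))


def _assign_probe_roles(config: GeneratorConfig, probe_ids: pd.Index):
    """Carve disjoint probe sets: reference, failing, high-missing, causal."""
    rng = _rng(config.seed, "probe_roles")
    n = config.n_probes
    n_ref = _resolve_n_reference(config)
    n_a = int(round(config.frac_causal_alpha * n))
    n_d = int(round(config.frac_causal_dbw * n))
    n_g = int(round(config.frac_causal_age * n))
    n_s = int(round(config.frac_causal_sex * n))
    total = n_ref + config.n_failing_probes + config.n_high_missing_probes + n_a + n_d + n_g + n_s
    if total > n:
        raise ConfigurationError(
            f"n_probes={n} too small to host reference ({n_ref}), failing "
            f"({config.n_failing_probes}), high-missing ({config.n_high_missing_probes}) "
            f"and causal ({n_a + n_d + n_g + n_s}) probe sets (need {total})"
        )
    order = rng.permutation(n)
    cuts = np.cumsum([n_ref, config.n_failing_probes, config.n_high_missing_probes, n_a, n_d, n_g, n_s])
    parts = np.split(order, cuts)[:7]
    ref, fail, hmiss, ca, cd, cg, cs = (probe_ids[np.sort(p)] for p in parts)
    return ref, fail, hmiss, ca, cd, cg, cs


def generate_methylation(cohort: TwinCohort, config: GeneratorConfig):
    """Generate beta / M / U / detection-p matrices plus the truth record.

    Per probe, a sample's logit methylation is: baseline (or the logit of the
    reference-mixture beta on cell-type discriminating probes) + shared pair
    effect + plate/well/sentrix offsets + individual noise, with planted
    effects added to the smaller twin at causal probes.  M and U intensities
    are constructed so ``M / (M + U + 100)`` reproduces beta exactly.

    Returns ``(beta: MethylationMatrix, M, U, detection_p: DataFrame, TruthRecord)``.
    """
    config.validate()
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(config.n_probes)], name="probe_id")
    ref_probes, fail_probes, hmiss_probes, ca, cd, cgp, cs = _assign_probe_roles(config, probe_ids)

    data = cohort.data
    prim = cohort.primary
    samples = data["sample_id"].tolist()
    n_probes, n_samples = config.n_probes, len(data)
    probe_pos = pd.Series(np.arange(n_probes), index=probe_ids)

    # baseline: bimodal on beta scale, spread on logit scale
    rng_base = _rng(config.seed, "baseline")
    peak = np.where(rng_base.random(n_probes) < 0.5, *config.baseline_peaks)
    baseline = logit(peak) + rng_base.normal(0.0, config.baseline_sd, n_probes)

    # reference profiles and per-sample compositions
    rng_ref = _rng(config.seed, "reference")
    R = rng_ref.uniform(0.05, 0.95, size=(len(ref_probes), config.n_cell_types))
    reference = pd.DataFrame(R, index=ref_probes, columns=list(config.cell_types))
    rng_w = _rng(config.seed, "compositions")
    W_prim = rng_w.dirichlet(config.dirichlet_conc, size=len(prim))
    comp = pd.DataFrame(W_prim, index=prim["sample_id"].to_numpy(), columns=list(config.cell_types))
    # replicates share their source sample's composition (same DNA)
    W = comp.reindex(data["is_replicate_of"].fillna(data["sample_id"]).to_numpy()).to_numpy()

    L = np.tile(baseline[:, None], (1, n_samples))
    ref_idx = probe_pos[ref_probes].to_numpy()
    mix_beta = np.clip(R @ W.T, 1e-6, 1 - 1e-6)
    L[ref_idx, :] = logit(mix_beta)

    # pair random effects: shared within pair, independent (and inflated) for bad pairs
    rng_u = _rng(config.seed, "pair_effects")
    pair_order = prim["pair_id"].drop_duplicates().tolist()
    bad_pairs = list(rng_u.choice(pair_order, size=config.n_bad_pairs, replace=False)) \
        if config.n_bad_pairs else []
    bad_set = set(bad_pairs)
    pair_u = {}
    for pid in pair_order:
        if pid in bad_set:
            pair_u[pid] = (rng_u.normal(0, config.bad_pair_sd, n_probes),
                           rng_u.normal(0, config.bad_pair_sd, n_probes))
        else:
            u = rng_u.normal(0, config.pair_sd, n_probes)
            pair_u[pid] = (u, u)
    seen: dict = {}
    for col, row in enumerate(data.itertuples(index=False)):
        pid = row.pair_id
        k = seen.get(pid, 0)
        if pd.isna(row.is_replicate_of):
            L[:, col] += pair_u[pid][min(k, 1)]
            seen[pid] = k + 1
    # replicate columns inherit the source twin's full signal later

    # batch offsets per probe x level
    rng_b = _rng(config.seed, "batch")
    for factor in ("plate", "well", "sentrix_position"):
        levels = sorted(data[factor].unique())
        offs = rng_b.normal(0, config.batch_sd, size=(n_probes, len(levels)))
        level_idx = data[factor].map({lv: i for i, lv in enumerate(levels)}).to_numpy()
        L += offs[:, level_idx]

    # individual noise on primary samples
    rng_e = _rng(config.seed, "noise")
    is_primary = data["is_replicate_of"].isna().to_numpy()
    L[:, is_primary] += rng_e.normal(0, config.individual_sd, size=(n_probes, int(is_primary.sum())))

    # planted effects on the smaller twin of each pair
    pairs = cohort.pairs().set_index("pair_id")
    dbw_pct = 100.0 * (pairs["bw_bigger"] - pairs["bw_smaller"]) / pairs["bw_bigger"]
    smaller_mask = (data["twin_role"] == "smaller").to_numpy() & is_primary
    pair_of = data["pair_id"].to_numpy()
    age_of = data["age"].to_numpy().astype(float)
    female_of = (data["sex"] == "female").to_numpy().astype(float)
    dbw_of = dbw_pct.reindex(pair_of).to_numpy()

    def _plant(probes, per_sample_mult, effect):
        if len(probes) == 0:
            return
        idx = probe_pos[probes].to_numpy()
        contrib = effect * per_sample_mult * smaller_mask
        L[np.ix_(idx, np.arange(n_samples))] += contrib[None, :]

    _plant(ca, np.ones(n_samples), config.alpha_true)
    _plant(cd, dbw_of, config.beta_dbw_true)
    _plant(cgp, age_of, config.delta_age_true)
    _plant(cs, female_of, config.gamma_sex_true)

    # replicate columns: source twin's logit + replicate noise
    rng_rep = _rng(config.seed, "replicates")
    col_of = {sid: i for i, sid in enumerate(samples)}
    rep_rows = data[data["is_replicate_of"].notna()]
    replicate_pair = rep_rows["pair_id"].iloc[0] if len(rep_rows) else None
    fail_idx = probe_pos[fail_probes].to_numpy()
    rep_cols = []
    for row in rep_rows.itertuples(index=False):
        col = col_of[row.sample_id]
        src = col_of[row.is_replicate_of]
        L[:, col] = L[:, src] + rng_rep.normal(0, config.replicate_sd, n_probes)
        rep_cols.append(col)

    beta = np.clip(expit(L), 1e-8, 1 - 1e-8)

    # planted unstable probes: replicate measurements scatter widely on beta scale
    if len(fail_idx) and rep_cols:
        beta[np.ix_(fail_idx, rep_cols)] = rng_rep.uniform(0.2, 0.8, size=(len(fail_idx), len(rep_cols)))

    # detection p-values: near zero, with planted high-missingness probes
    rng_p = _rng(config.seed, "detection_p")
    detp = rng_p.uniform(0.0, 0.005, size=(n_probes, n_samples))
    sporadic = rng_p.random((n_probes, n_samples)) < config.sporadic_missing_rate
    detp[sporadic] = rng_p.uniform(0.011, 0.5, size=int(sporadic.sum()))
    n_miss = int(np.floor(0.05 * n_samples)) + 1  # strictly > 5% of samples
    for pi in probe_pos[hmiss_probes].to_numpy():
        cols = rng_p.choice(n_samples, size=n_miss, replace=False)
        detp[pi, cols] = rng_p.uniform(0.011, 0.5, size=n_miss)

    # intensities reproducing beta exactly under M / (M + U + 100)
    C = np.maximum(10_100.0, 200.0 / (1.0 - beta))
    M = beta * C
    U = C - 100.0 - M

    beta_df = pd.DataFrame(beta, index=probe_ids, columns=samples)
    truth = TruthRecord(
        causal_alpha={p: config.alpha_true for p in ca},
        causal_dbw={p: config.beta_dbw_true for p in cd},
        causal_age={p: config.delta_age_true for p in cgp},
        causal_sex={p: config.gamma_sex_true for p in cs},
        compositions=pd.DataFrame(W, index=samples, columns=list(config.cell_types)),
        reference=reference,
        failing_probes=list(fail_probes),
        high_missing_probes=list(hmiss_probes),
        bad_pairs=sorted(bad_pairs),
        replicate_pair=replicate_pair,
    )
    truth.validate(probe_ids)
    mat = MethylationMatrix(beta_df, scale="beta")
    Mdf = pd.DataFrame(M, index=probe_ids, columns=samples)
    Udf = pd.DataFrame(U, index=probe_ids, columns=samples)
    Pdf = pd.DataFrame(detp, index=probe_ids, columns=samples)
    return mat, Mdf, Udf, Pdf, truth


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixture(cohort: TwinCohort, matrices: dict, truth: TruthRecord, out_dir) -> dict:
    """Write a complete fixture: sample sheet, matrices, reference, truth.

    ``matrices`` maps names among {"beta", "M", "U", "detection_p"} to a
    MethylationMatrix or DataFrame.  Returns the paths written.
    """
    if cohort.n_pairs == 0 or len(cohort.data) == 0:
        raise ValidationError("refusing to write a fixture for an empty cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    sheet = out / "samples.csv"
    cohort.to_csv(sheet)
    paths["samples"] = sheet
    for name, m in matrices.items():
        p = out / f"{name}.tsv.gz"
        if isinstance(m, MethylationMatrix):
            m.to_tsv(p)
        else:
            df = m.copy()
            df.index.name = "probe_id"
            df.to_csv(p, sep="\t", na_rep="NA")
        paths[name] = p
    tpath = out / "truth.json"
    truth.to_json(tpath)
    paths["truth"] = tpath
    rpath = out / "cell_reference.tsv"
    ref = truth.reference.copy()
    ref.index.name = "probe_id"
    ref.to_csv(rpath, sep="\t")
    paths["reference"] = rpath
    return paths
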
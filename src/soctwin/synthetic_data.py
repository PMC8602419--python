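"""Twin-cohort container and synthetic cohort generation.

A twin cohort is a long-format table with one row per twin individual:
pair identifier, member index (1/2), zygosity (MZ / same-sex DZ /
opposite-sex DZ), sex, and numeric trait (and optionally polygenic-score)
columns.  The generator draws traits from the classical biometric
latent-factor model — additive genetic (A), shared environment (C),
dominance (D) and unique environment (E) — with the standard cross-twin
factor correlations (A: 1 in MZ, 0.5 in DZ; D: 1 in MZ, 0.25 in DZ;
C: 1 in both; E: 0), so every downstream estimator has a known ground
truth.  Cross-trait structure is induced by genetic and unique-environment
correlation matrices; traits are simulated on a standardized latent scale
and then affinely mapped to the configured per-sex mean/SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ZYGOSITIES = ("MZ", "DZss", "DZos")
SEXES = ("M", "F")
CORE_COLUMNS = ("pair_id", "member", "zygosity", "sex")

#: hidden column prefix storing each individual's standardized additive-genetic
#: deviate per trait (needed by attach_pgs; dropped on CSV export by default)
LATENT_PREFIX = "_A_"


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


class CohortError(ValueError):
    """A cohort table violates the twin-data invariants."""


# --------------------------------------------------------------------------
# cohort container


@dataclass
class TwinCohort:
    """Long-format twin dataset: one row per individual twin.

    ``data`` holds the table; ``traits`` and ``pgs_scores`` name the
    quantitative trait and polygenic-score columns.  Missing values are
    NaN, never sentinel-coded.  ``truth``, present on simulated cohorts,
    records the generating path coefficients per trait and sex.
    """

    data: pd.DataFrame
    traits: tuple[str, ...]
    pgs_scores: tuple[str, ...] = ()
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        self.pgs_scores = tuple(self.pgs_scores)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        for col in CORE_COLUMNS:
            if col not in df.columns:
                raise CohortError(f"missing required column {col!r}")
        if len(df) and not df["member"].isin([1, 2]).all():
            raise CohortError("member index must be 1 or 2")
        if len(df) and not df["zygosity"].isin(ZYGOSITIES).all():
            raise CohortError(f"zygosity must be one of {ZYGOSITIES}")
        if len(df) and not df["sex"].isin(SEXES).all():
            raise CohortError(f"sex must be one of {SEXES}")
        for trait in self.traits + self.pgs_scores:
            if trait not in df.columns:
                raise CohortError(f"missing trait column {trait!r}")
            if not pd.api.types.is_numeric_dtype(df[trait]):
                raise CohortError(f"trait column {trait!r} is not numeric")
        if not len(df):
            return
        grp = df.groupby("pair_id")
        if (grp.size() > 2).any():
            raise CohortError("a pair_id occurs more than twice")
        if (grp["member"].nunique() != grp.size()).any():
            raise CohortError("a pair has a duplicate member index")
        if (grp["zygosity"].nunique() > 1).any():
            raise CohortError("a pair has discordant zygosity codes")
        pairs = df[df["pair_id"].map(grp.size()) == 2]
        nsex = pairs.groupby("pair_id")["sex"].nunique()
        zyg = pairs.drop_duplicates("pair_id").set_index("pair_id")["zygosity"]
        if ((zyg == "DZos") & (nsex.reindex(zyg.index) != 2)).any():
            raise CohortError("a DZos pair has concordant sex")
        if ((zyg != "DZos") & (nsex.reindex(zyg.index) != 1)).any():
            raise CohortError("an MZ/DZss pair has discordant sex")

    # -- accessors ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_pairs(self) -> int:
        if not len(self.data):
            return 0
        return int((self.data.groupby("pair_id").size() == 2).sum())

    def pair_table(self, columns: list[str]) -> pd.DataFrame:
        """Wide table with one row per complete pair.

        Columns ``<name>_1`` / ``<name>_2`` hold member 1 / member 2 values
        of each requested column; ``zygosity`` plus per-member sex are kept.
        Pairs with a missing member or a missing value in any requested
        column are dropped.
        """
        df = self.data
        wide = df.pivot(index="pair_id", columns="member",
                        values=list(columns) + ["sex"])
        wide.columns = [f"{c}_{m}" for c, m in wide.columns]
        zyg = df.drop_duplicates("pair_id").set_index("pair_id")["zygosity"]
        wide["zygosity"] = zyg
        value_cols = [f"{c}_{m}" for c in columns for m in (1, 2)
                      if f"{c}_{m}" in wide.columns]
        need = [f"{c}_{m}" for c in list(columns) + ["sex"] for m in (1, 2)]
        missing = [c for c in need if c not in wide.columns]
        if missing:  # e.g. no member-2 rows at all
            return wide.iloc[0:0]
        wide = wide.dropna(subset=value_cols + ["sex_1", "sex_2"])
        wide[value_cols] = wide[value_cols].astype(float)
        return wide

    def pair_arrays(self, trait: str) -> dict[tuple[str, str | None], np.ndarray]:
        """Complete-pair (n, 2) value arrays keyed by (zygosity, sex).

        Same-sex groups are keyed by their shared sex; the key for
        opposite-sex DZ pairs is ("DZos", None) with column 0 holding the
        male member and column 1 the female member.
        """
        wide = self.pair_table([trait])
        out: dict[tuple[str, str | None], np.ndarray] = {}
        for zyg in ZYGOSITIES:
            sub = wide[wide["zygosity"] == zyg]
            if not len(sub):
                continue
            if zyg == "DZos":
                male_first = sub["sex_1"] == "M"
                a = np.where(male_first, sub[f"{trait}_1"], sub[f"{trait}_2"])
                b = np.where(male_first, sub[f"{trait}_2"], sub[f"{trait}_1"])
                out[("DZos", None)] = np.column_stack([a, b]).astype(float)
                continue
            for sex in SEXES:
                s = sub[sub["sex_1"] == sex]
                if len(s):
                    out[(zyg, sex)] = s[[f"{trait}_1", f"{trait}_2"]].to_numpy(float)
        return out

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, path_or_buf, include_latent: bool = False) -> None:
        """Write as CSV (empty fields for missing values).

        Hidden latent additive-genetic columns are dropped unless
        ``include_latent`` is set.
        """
        df = self.data
        if not include_latent:
            df = df[[c for c in df.columns if not c.startswith(LATENT_PREFIX)]]
        df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, traits: list[str] | None = None,
                 pgs_scores: list[str] | None = None) -> "TwinCohort":
        """Read a cohort CSV.

        When ``traits``/``pgs_scores`` are not given, columns named
        ``pgs_*`` are taken as scores and all remaining non-core columns
        as traits.
        """
        df = pd.read_csv(path_or_buf)
        extra = [c for c in df.columns
                 if c not in CORE_COLUMNS and not c.startswith(LATENT_PREFIX)]
        if pgs_scores is None:
            pgs_scores = [c for c in extra if c.startswith("pgs_")]
        if traits is None:
            traits = [c for c in extra if c not in set(pgs_scores)]
        return cls(df, tuple(traits), tuple(pgs_scores))


# --------------------------------------------------------------------------
# simulation configuration


@dataclass
class TraitSpec:
    """Per-sex moments and standardized variance proportions of one trait."""

    mean: dict[str, float]
    sd: dict[str, float]
    a2: dict[str, float]
    c2: dict[str, float] = field(default_factory=lambda: {"M": 0.0, "F": 0.0})
    d2: dict[str, float] = field(default_factory=lambda: {"M": 0.0, "F": 0.0})
    e2: dict[str, float] = field(default_factory=dict)

    @classmethod
    def symmetric(cls, mean: float, sd: float, a2: float,
                  c2: float = 0.0, d2: float = 0.0) -> "TraitSpec":
        """Identical structure in both sexes; e² fills the remainder."""
        e2 = 1.0 - a2 - c2 - d2
        return cls({s: mean for s in SEXES}, {s: sd for s in SEXES},
                   {s: a2 for s in SEXES}, {s: c2 for s in SEXES},
                   {s: d2 for s in SEXES}, {s: e2 for s in SEXES})

    @classmethod
    def by_sex(cls, mean_m: float, sd_m: float, a2_m: float,
               mean_f: float, sd_f: float, a2_f: float) -> "TraitSpec":
        """AE trait with sex-specific mean, SD and heritability."""
        return cls({"M": mean_m, "F": mean_f}, {"M": sd_m, "F": sd_f},
                   {"M": a2_m, "F": a2_f},
                   e2={"M": 1 - a2_m, "F": 1 - a2_f})

    def proportions(self, sex: str) -> tuple[float, float, float, float]:
        return (self.a2[sex], self.c2[sex], self.d2[sex], self.e2[sex])


@dataclass
class SimulationConfig:
    """Ground-truth structure of a simulated twin cohort.

    ``rA``/``rE`` are cross-trait correlation matrices of the additive
    genetic and unique-environment factors (identity = independent traits);
    they are shared between the sexes while the per-trait variance shares
    may differ by sex.  ``rg`` is the cross-sex additive-genetic correlation
    applied to opposite-sex pairs (1 = no sex-specific genetic factors).
    """

    n_mz_pairs: int
    n_dzss_pairs: int
    n_dzos_pairs: int
    traits: dict[str, TraitSpec]
    n_singletons: int = 0
    rA: np.ndarray | None = None
    rE: np.ndarray | None = None
    rg: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.traits)
        if self.rA is None:
            self.rA = np.eye(k)
        if self.rE is None:
            self.rE = np.eye(k)
        self.rA = np.asarray(self.rA, float)
        self.rE = np.asarray(self.rE, float)
        self.validate()

    def validate(self) -> None:
        if min(self.n_mz_pairs, self.n_dzss_pairs, self.n_dzos_pairs,
               self.n_singletons) < 0:
            raise ConfigurationError("group sizes must be nonnegative")
        if self.n_mz_pairs + self.n_dzss_pairs + self.n_dzos_pairs == 0:
            raise ConfigurationError("at least one pair group must be nonempty")
        if not 0.0 <= self.rg <= 1.0:
            raise ConfigurationError("rg must lie in [0, 1]")
        for name, spec in self.traits.items():
            for sex in SEXES:
                if sex not in spec.a2 or sex not in spec.e2:
                    raise ConfigurationError(
                        f"trait {name!r}, sex {sex}: missing a2/e2")
                a2, c2, d2, e2 = spec.proportions(sex)
                if min(a2, c2, d2, e2) < 0:
                    raise ConfigurationError(
                        f"trait {name!r}, sex {sex}: negative variance proportion")
                if abs(a2 + c2 + d2 + e2 - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"trait {name!r}, sex {sex}: proportions sum to "
                        f"{a2 + c2 + d2 + e2!r}, not 1")
                if c2 > 0 and d2 > 0:
                    raise ConfigurationError(
                        f"trait {name!r}, sex {sex}: C and D cannot both be "
                        "present (twins reared together cannot separate them)")
        k = len(self.traits)
        for label, mat in (("rA", self.rA), ("rE", self.rE)):
            if mat.shape != (k, k):
                raise ConfigurationError(f"{label} must be {k}x{k}")
            if not np.allclose(mat, mat.T) or not np.allclose(np.diag(mat), 1.0):
                raise ConfigurationError(f"{label} must be a correlation matrix")
            if np.linalg.eigvalsh(mat).min() < -1e-10:
                raise ConfigurationError(f"{label} is not positive semidefinite")


# --------------------------------------------------------------------------
# generation

_RHO_D = {"MZ": 1.0, "DZss": 0.25, "DZos": 0.25}


def _correlated_pair_factors(rng: np.random.Generator, n: int, k: int,
                             rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Two (n, k) standard-normal blocks with coordinatewise correlation rho.

    rho == 1 returns the identical array twice (exact sharing).
    """
    if rho >= 1.0:
        shared = rng.standard_normal((n, k))
        return shared, shared
    shared = rng.standard_normal((n, k))
    u1 = rng.standard_normal((n, k))
    u2 = rng.standard_normal((n, k))
    s, u = np.sqrt(rho), np.sqrt(1.0 - rho)
    return s * shared + u * u1, s * shared + u * u2


def _safe_chol(corr: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, tolerating semidefinite correlation matrices."""
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def simulate_cohort(config: SimulationConfig) -> TwinCohort:
    """Draw a twin cohort under the configured biometric structure.

    By construction the standardized within-pair trait covariance equals
    a²+c²+d² (MZ), 0.5a²+c²+0.25d² (same-sex DZ) and 0.5·rg·a_m·a_f + c²
    (opposite-sex DZ); identical config (including seed) reproduces the
    cohort bitwise.  Singletons are generated as full pairs with one member
    deleted, cycling through the zygosity groups.
    """
    rng = np.random.default_rng(config.seed)
    names = list(config.traits)
    k = len(names)
    LA = _safe_chol(config.rA)
    LE = _safe_chol(config.rE)
    scale = {
        comp: {s: np.sqrt([getattr(config.traits[t], comp)[s] for t in names])
               for s in SEXES}
        for comp in ("a2", "c2", "d2", "e2")
    }
    means = {s: np.array([config.traits[t].mean[s] for t in names]) for s in SEXES}
    sds = {s: np.array([config.traits[t].sd[s] for t in names]) for s in SEXES}

    frames: list[pd.DataFrame] = []
    counter = [0]

    def draw_group(zyg: str, n: int, tag: str) -> pd.DataFrame | None:
        if n == 0:
            return None
        rho_a = 0.5 * config.rg if zyg == "DZos" else (1.0 if zyg == "MZ" else 0.5)
        g1, g2 = _correlated_pair_factors(rng, n, k, rho_a)
        c_sh = rng.standard_normal((n, k))
        d1, d2_ = _correlated_pair_factors(rng, n, k, _RHO_D[zyg])
        e1 = rng.standard_normal((n, k)) @ LE.T
        e2_ = rng.standard_normal((n, k)) @ LE.T
        A1, A2 = g1 @ LA.T, g2 @ LA.T  # standardized genetic deviates

        if zyg == "DZos":
            m_first = np.arange(n) % 2 == 0
            sex1 = np.where(m_first, "M", "F")
            sex2 = np.where(m_first, "F", "M")
        else:
            n_m = (n + 1) // 2
            sex1 = sex2 = np.array(["M"] * n_m + ["F"] * (n - n_m))

        pids = np.array([f"{tag}{counter[0] + i:05d}" for i in range(n)])
        counter[0] += n

        member_frames = []
        for member, (A, C, D, E, sex) in enumerate(
                [(A1, c_sh, d1, e1, sex1), (A2, c_sh, d2_, e2_, sex2)], 1):
            male = (sex == "M")[:, None]

            def per_sex(table):
                return np.where(male, table["M"], table["F"])

            y_std = (per_sex(scale["a2"]) * A + per_sex(scale["c2"]) * C
                     + per_sex(scale["d2"]) * D + per_sex(scale["e2"]) * E)
            y = per_sex(means) + per_sex(sds) * y_std
            df = pd.DataFrame({"pair_id": pids, "member": member,
                               "zygosity": zyg, "sex": sex})
            for j, t in enumerate(names):
                df[t] = y[:, j]
            for j, t in enumerate(names):
                df[LATENT_PREFIX + t] = A[:, j]
            member_frames.append(df)
        out = pd.concat(member_frames, ignore_index=True)
        return out.sort_values(["pair_id", "member"], kind="stable",
                               ignore_index=True)

    for zyg, n, tag in (("MZ", config.n_mz_pairs, "MZ"),
                        ("DZss", config.n_dzss_pairs, "DS"),
                        ("DZos", config.n_dzos_pairs, "DO")):
        df = draw_group(zyg, n, tag)
        if df is not None:
            frames.append(df)

    # singletons: pairs with member 2 removed, cycling zygosity groups
    if config.n_singletons:
        per = {z: 0 for z in ZYGOSITIES}
        for i in range(config.n_singletons):
            per[ZYGOSITIES[i % 3]] += 1
        for zyg in ZYGOSITIES:
            if per[zyg]:
                df = draw_group(zyg, per[zyg], "SG")
                frames.append(df[df["member"] == 1].reset_index(drop=True))

    data = pd.concat(frames, ignore_index=True)
    truth = {
        "traits": {t: {s: dict(zip(("a2", "c2", "d2", "e2"),
                                   config.traits[t].proportions(s)))
                       for s in SEXES} for t in names},
        "rA": config.rA.copy(), "rE": config.rE.copy(), "rg": config.rg,
    }
    return TwinCohort(data, tuple(names), truth=truth)


# --------------------------------------------------------------------------
# polygenic scores


def attach_pgs(cohort: TwinCohort, trait: str, pgs_R2: float, seed: int,
               name: str | None = None) -> TwinCohort:
    """Add a standardized polygenic-score column for ``trait``.

    The score is a unit-variance mixture of the individual's standardized
    additive-genetic deviate for the trait and an independent purely
    genetic factor (cross-twin correlation 1 in MZ, 0.5 in DZ), weighted so
    that the population squared correlation of score and trait equals
    ``pgs_R2`` within each sex.  Being a function of genetic factors only,
    co-twin scores correlate exactly 1 in MZ pairs and 0.5 in DZ pairs in
    expectation (exactly 1 in MZ by construction).
    """
    if trait not in cohort.traits:
        raise ConfigurationError(f"unknown trait {trait!r}")
    if not 0.0 <= pgs_R2 < 1.0:
        raise ConfigurationError("pgs_R2 must lie in [0, 1)")
    lat_col = LATENT_PREFIX + trait
    if lat_col not in cohort.data.columns or cohort.truth is None:
        raise ConfigurationError(
            f"cohort lacks the latent genetic factor for {trait!r}; "
            "attach_pgs requires a simulated cohort")
    for sex in SEXES:
        a2 = cohort.truth["traits"][trait][sex]["a2"]
        if pgs_R2 > a2 + 1e-12:
            raise ConfigurationError(
                f"pgs_R2={pgs_R2} exceeds the heritability a²={a2} of "
                f"{trait!r} for sex {sex}; a genetic score cannot explain "
                "more than the additive-genetic share of the trait")

    df = cohort.data.copy()
    rng = np.random.default_rng(seed)

    # independent genetic factor with the A-type twin correlation structure
    pid_codes, pid_idx = np.unique(df["pair_id"].to_numpy(), return_inverse=True)
    shared = rng.standard_normal(len(pid_codes))[pid_idx]
    unique = rng.standard_normal(len(df))
    w = np.where(df["zygosity"].to_numpy() == "MZ", 1.0, 0.5)
    noise = np.sqrt(w) * shared + np.sqrt(1.0 - w) * unique

    lat = df[lat_col].to_numpy()
    a_path = np.where(df["sex"].to_numpy() == "M",
                      np.sqrt(cohort.truth["traits"][trait]["M"]["a2"]),
                      np.sqrt(cohort.truth["traits"][trait]["F"]["a2"]))
    # corr(score, trait) = alpha * a  =>  alpha = sqrt(R2)/a  per sex
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(a_path > 0, np.sqrt(pgs_R2) / a_path, 0.0)
    score = alpha * lat + np.sqrt(np.clip(1.0 - alpha**2, 0.0, None)) * noise

    col = name or f"pgs_{trait}"
    df[col] = score
    return TwinCohort(df, cohort.traits, cohort.pgs_scores + (col,),
                      truth=cohort.truth)


# --------------------------------------------------------------------------
# filtering


def complete_pairs(cohort: TwinCohort,
                   traits: list[str] | None = None) -> tuple[TwinCohort, int]:
    """Keep only pairs with both members present and non-missing traits.

    Returns the filtered cohort and the number of individuals removed
    (singleton twins plus members of pairs incomplete for the requested
    traits).
    """
    use = list(traits) if traits is not None else list(cohort.traits)
    df = cohort.data
    if not len(df):
        return cohort, 0
    ok_value = df[use].notna().all(axis=1) if use else pd.Series(True, index=df.index)
    counts = df[ok_value].groupby("pair_id")["member"].nunique()
    keep_pairs = set(counts[counts == 2].index)
    keep = df["pair_id"].isin(keep_pairs) & ok_value
    removed = int(len(df) - keep.sum())
    out = df[keep].reset_index(drop=True)
    return TwinCohort(out, cohort.traits, cohort.pgs_scores,
                      truth=cohort.truth), removed
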
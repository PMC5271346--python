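"""Synthetic longitudinal airway-microbiome cohort generator.

Emulates the sampling design of a ventilated-preterm-infant cohort:
tracheal aspirates targeted at enrollment (~day 3), 7, 14 and 21 days of
age with +/- 48 h jitter; 2-4 samples per subject (median 2) after
visit-level missingness; per-sample sequencing depth drawn log-uniform
in the observed range [6451, 196691]; communities dominated by
*Staphylococcus* and *Ureaplasma*; outcome groups mild / moderate /
severe with sizes 25 / 30 / 39.

Generative model, per subject i in group g:

* random intercepts b_i ~ Normal(0, re_sd^2), one per target taxon;
* target-taxon mean relative abundance at age t follows the join-point
  logit curve  logit(mu) = b0_g + b1_g t + b2_g (t - knot)_+ + b_i ;
* the target-taxon count is beta-binomial: p ~ Beta(mu/phi_g,
  (1-mu)/phi_g), y ~ Binomial(depth, p) — matching the inferential
  model's mean/dispersion parameterisation so parameter recovery is
  well-posed;
* the non-target composition evolves as a Dirichlet random walk with
  group-specific concentration (lower concentration => more turnover),
  and fills the remaining depth multinomially;
* bacterial load: load_log10 = intercept + slope * (t / 7) + Normal(0, sd^2).

A ``TruthRecord`` keeps every generator knob and the per-subject latent
intercepts, serialised as a flat key-value text file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_data import SampleMetadata, TaxonCountTable

__all__ = [
    "SyntheticCohortConfig",
    "TruthRecord",
    "generate_cohort",
    "generate_null_cohort",
    "STAPH",
    "UREA",
]

STAPH = "Staphylococcus"
UREA = "Ureaplasma"

#: Default per-group join-point logit-linear trajectories
#: (intercept, pre-knot slope, post-knot slope change), knot at day 10.
#: Staphylococcus rises faster and higher in milder outcomes; Ureaplasma
#: starts higher in severe outcomes.
_STAPH_DEFAULT = {
    "mild": (-2.0, 0.25, -0.20),
    "moderate": (-2.0, 0.18, -0.15),
    "severe": (-2.0, 0.10, -0.08),
}
_UREA_DEFAULT = {
    "mild": (-3.5, 0.05, -0.05),
    "moderate": (-2.8, 0.05, -0.05),
    "severe": (-2.2, 0.05, -0.05),
}


class ConfigError(ValueError):
    """Raised for inconsistent generator configuration."""


@dataclass
class SyntheticCohortConfig:
    """All generator knobs. Fixed seed implies bit-identical output."""

    n_subjects_per_group: dict[str, int] = field(
        default_factory=lambda: {"mild": 25, "moderate": 30, "severe": 39}
    )
    collection_days: tuple[int, ...] = (3, 7, 14, 21)
    jitter_days: int = 2
    #: per-visit miss probability; subjects are redrawn until >= 2 visits
    #: remain, which at 0.55 gives 2-4 samples/subject with median 2
    missingness: float = 0.55
    depth_range: tuple[int, int] = (6451, 196691)
    n_taxa: int = 18
    #: group -> Dirichlet random-walk concentration (lower => more turnover)
    drift_concentration: dict[str, float] = field(
        default_factory=lambda: {"mild": 15.0, "moderate": 4.0, "severe": 1.0}
    )
    staph_trajectory: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_STAPH_DEFAULT)
    )
    urea_trajectory: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_UREA_DEFAULT)
    )
    knot_day: float = 10.0
    #: group -> beta-binomial overdispersion phi (0 = pure binomial)
    dispersion: dict[str, float] = field(
        default_factory=lambda: {"mild": 0.08, "moderate": 0.18, "severe": 0.30}
    )
    re_sd: float = 0.8
    load_intercept: float = 3.75
    load_slope_per_week: float = 1.05
    load_sd: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.missingness <= 1.0:
            raise ConfigError(f"missingness {self.missingness} outside [0, 1]")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ConfigError(f"depth_range {self.depth_range} must be positive and ordered")
        if self.n_taxa < 3:
            raise ConfigError("need at least 3 taxa (2 targets + background)")
        if self.re_sd < 0 or self.load_sd < 0:
            raise ConfigError("standard deviations must be non-negative")
        for g in self.n_subjects_per_group:
            for name, table in (
                ("staph_trajectory", self.staph_trajectory),
                ("urea_trajectory", self.urea_trajectory),
                ("dispersion", self.dispersion),
                ("drift_concentration", self.drift_concentration),
            ):
                if g not in table:
                    raise ConfigError(f"group {g!r} has no entry in {name}")
        for g, c in self.drift_concentration.items():
            if c <= 0:
                raise ConfigError(f"drift_concentration[{g!r}] must be > 0")
        for g, p in self.dispersion.items():
            if p < 0:
                raise ConfigError(f"dispersion[{g!r}] must be >= 0")


@dataclass
class TruthRecord:
    """Every generating parameter plus per-subject latent values."""

    config: SyntheticCohortConfig
    #: subject_id -> (group, b_staph, b_urea)
    latents: pd.DataFrame

    def to_file(self, path) -> None:
        """Flat ``key<TAB>value`` text serialisation (round-trippable)."""
        cfg = self.config
        with open(path, "w") as fh:
            def put(k, v):
                fh.write(f"{k}\t{v!r}\n")

            put("collection_days", tuple(cfg.collection_days))
            put("jitter_days", cfg.jitter_days)
            put("missingness", cfg.missingness)
            put("depth_range", tuple(cfg.depth_range))
            put("n_taxa", cfg.n_taxa)
            put("knot_day", cfg.knot_day)
            put("re_sd", cfg.re_sd)
            put("load_intercept", cfg.load_intercept)
            put("load_slope_per_week", cfg.load_slope_per_week)
            put("load_sd", cfg.load_sd)
            put("seed", cfg.seed)
            for g in cfg.n_subjects_per_group:
                put(f"n_subjects[{g}]", cfg.n_subjects_per_group[g])
                put(f"drift_concentration[{g}]", cfg.drift_concentration[g])
                put(f"staph_trajectory[{g}]", tuple(cfg.staph_trajectory[g]))
                put(f"urea_trajectory[{g}]", tuple(cfg.urea_trajectory[g]))
                put(f"dispersion[{g}]", cfg.dispersion[g])
            for sid, row in self.latents.iterrows():
                put(f"latent[{sid}]", (row["group"], row["b_staph"], row["b_urea"]))

    @staticmethod
    def read_file(path) -> dict:
        """Parse the flat key-value serialisation back into a dict."""
        import ast

        out = {}
        with open(path) as fh:
            for line in fh:
                key, _, value = line.rstrip("\n").partition("\t")
                out[key] = ast.literal_eval(value)
        return out


def _joinpoint_logit(t: np.ndarray, coef, knot: float) -> np.ndarray:
    b0, b1, b2 = coef
    return b0 + b1 * t + b2 * np.clip(t - knot, 0.0, None)


def _draw_visit_days(rng, cfg: SyntheticCohortConfig) -> np.ndarray:
    """Jittered target days, redrawn until distinct; sorted ascending."""
    targets = np.asarray(cfg.collection_days)
    for _ in range(200):
        if cfg.jitter_days > 0:
            days = targets + rng.integers(-cfg.jitter_days, cfg.jitter_days + 1, targets.size)
        else:
            days = targets.copy()
        days = np.maximum(days, 0)
        if len(np.unique(days)) == len(days):
            return np.sort(days)
    raise RuntimeError("could not draw distinct visit days")  # pragma: no cover


def _beta_binomial(rng, n: int, mu: float, phi: float) -> int:
    mu = float(np.clip(mu, 1e-9, 1 - 1e-9))
    if phi <= 0:
        return int(rng.binomial(n, mu))
    p = rng.beta(mu / phi, (1 - mu) / phi)
    return int(rng.binomial(n, p))


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[TaxonCountTable, SampleMetadata, TruthRecord]:
    """Draw one full longitudinal cohort from the generative model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_bg = config.n_taxa - 2
    taxon_ids = [STAPH, UREA] + [f"taxon_{i:02d}" for i in range(1, n_bg + 1)]

    sample_ids: list[str] = []
    count_rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    latent_rows: list[dict] = []

    log_lo, log_hi = np.log(config.depth_range[0]), np.log(config.depth_range[1])
    n_visits = len(config.collection_days)

    for group, n_sub in config.n_subjects_per_group.items():
        staph_coef = config.staph_trajectory[group]
        urea_coef = config.urea_trajectory[group]
        phi = config.dispersion[group]
        conc = config.drift_concentration[group]
        for i in range(n_sub):
            subject = f"{group}_{i + 1:03d}"
            days = _draw_visit_days(rng, config)
            # visit-level missingness, conditioned on >= 2 retained visits
            for _ in range(1000):
                keep = rng.random(n_visits) > config.missingness
                if keep.sum() >= min(2, n_visits):
                    break
            days = days[keep]
            b_staph = rng.normal(0.0, config.re_sd)
            b_urea = rng.normal(0.0, config.re_sd)
            latent_rows.append(
                {"subject_id": subject, "group": group, "b_staph": b_staph, "b_urea": b_urea}
            )
            # background composition: Dirichlet random walk across visits
            pi = rng.dirichlet(np.ones(n_bg))
            for day in days:
                t = float(day)
                mu_s = expit(_joinpoint_logit(np.array(t), staph_coef, config.knot_day) + b_staph)
                mu_u = expit(_joinpoint_logit(np.array(t), urea_coef, config.knot_day) + b_urea)
                if mu_s + mu_u > 0.95:  # cap so background keeps support
                    scale = 0.95 / (mu_s + mu_u)
                    mu_s, mu_u = mu_s * scale, mu_u * scale
                depth = int(np.round(np.exp(rng.uniform(log_lo, log_hi))))
                y_s = _beta_binomial(rng, depth, float(mu_s), phi)
                rest = depth - y_s
                y_u = _beta_binomial(rng, rest, float(mu_u / (1 - mu_s)), phi) if rest else 0
                bg_total = rest - y_u
                bg = rng.multinomial(bg_total, pi) if bg_total else np.zeros(n_bg, dtype=int)
                row = np.concatenate(([y_s, y_u], bg))
                if row.sum() == 0:  # pragma: no cover - depth >= 1 always
                    row[0] = 1
                sid = f"{subject}_d{int(day):02d}"
                sample_ids.append(sid)
                count_rows.append(row)
                load = (
                    config.load_intercept
                    + config.load_slope_per_week * (t / 7.0)
                    + rng.normal(0.0, config.load_sd)
                )
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "subject_id": subject,
                        "collection_day": int(day),
                        "group": group,
                        "bacterial_load_log10": load,
                    }
                )
                # walk the background composition to the next visit
                pi = rng.dirichlet(conc * pi + 0.1)

    table = TaxonCountTable(
        sample_ids=sample_ids,
        taxon_ids=taxon_ids,
        counts=np.vstack(count_rows),
    )
    meta = SampleMetadata(
        frame=pd.DataFrame(meta_rows).set_index("sample_id"),
        group_labels=tuple(config.n_subjects_per_group),
    )
    truth = TruthRecord(
        config=config, latents=pd.DataFrame(latent_rows).set_index("subject_id")
    )
    return table, meta, truth


def generate_null_cohort(
    config: SyntheticCohortConfig,
) -> tuple[TaxonCountTable, SampleMetadata, TruthRecord]:
    """Same generator with every group-specific parameter forced equal.

    All groups receive the parameters of the first declared group label, so
    any downstream group comparison is testing a true null.
    """
    config.validate()
    first = next(iter(config.n_subjects_per_group))
    groups = list(config.n_subjects_per_group)
    null_cfg = replace(
        config,
        drift_concentration={g: config.drift_concentration[first] for g in groups},
        staph_trajectory={g: tuple(config.staph_trajectory[first]) for g in groups},
        urea_trajectory={g: tuple(config.urea_trajectory[first]) for g in groups},
        dispersion={g: config.dispersion[first] for g in groups},
    )
    return generate_cohort(null_cfg)
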
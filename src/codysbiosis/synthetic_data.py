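"""Synthetic two-group, two-kingdom cohort generator.

Emulates a small case-control metagenomic study (cases "ARFC", controls
"HC"; default 19 vs 17 children) at genus level, so that every downstream
stage — diversity, biomarker discovery, cross-kingdom correlation networks,
classification, pathway aggregation — can be exercised and validated without
external sequencing data.

The generator is a Gaussian copula: per group it draws a latent multivariate
normal whose correlation matrix embeds each planted bacterium-fungus coupling
(and each taxon-IgE coupling) via the exact bivariate-normal inversion
``r = 2 sin(pi * rho_s / 6)`` of a target Spearman coefficient.  Because
Spearman correlation is rank-based, the target survives the subsequent
monotone margin transform to a lognormal abundance scale.  Margins are then
optionally zero-inflated (structural absences) and total-sum scaled per
kingdom into relative fractions.

Total IgE is drawn per group from a lognormal matched by moments to the
group's mean +/- SD and rank-coupled to selected fungi through the same
latent copula, so the planted quantity is exactly a Spearman correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import AbundanceTable, SampleMetadata

CASE, CONTROL = "ARFC", "HC"


def spearman_to_pearson(rho_s: float) -> float:
    """Latent Pearson correlation reproducing a target Spearman under a
    bivariate Gaussian copula: ``r = 2 sin(pi * rho_s / 6)``.

    |r| >= |rho_s| with the sign preserved; exact for bivariate normal.
    """
    if abs(rho_s) > 1:
        raise ValueError(f"|rho_s| must be <= 1, got {rho_s}")
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


@dataclass(frozen=True)
class PlantedEdge:
    """A bacterium-fungus pair with a target Spearman correlation."""

    bacterial_taxon: str
    fungal_taxon: str
    target_spearman: float

    def __post_init__(self) -> None:
        if not (0 < abs(self.target_spearman) < 1):
            raise ValueError(
                "target_spearman must be in (-1, 1) excluding 0, got "
                f"{self.target_spearman}"
            )


# Focal taxa given real genus names so reports read like the data they mimic.
FOCAL_FUNGI = (
    "Dentiscutata", "Cenococcum", "Ambispora", "Saccharomyces",
    "Patellaria", "Acaromyces", "Mycoemilia", "Tulasnellaceae_unclassified",
    "Enteropsectra",
)
FOCAL_BACTERIA = (
    "Bacillus", "Dielma", "Flavonifractor", "Anaerostipes", "Subdoligranulum",
)


def _default_depleted():
    # (taxon, mean fraction in controls, mean fraction in cases)
    return [
        ("Dentiscutata", 0.0370, 0.0149),
        ("Cenococcum", 0.0174, 0.0030),
    ]


def _default_ige_coupling():
    # fungal genera rank-coupled to total IgE (cohort-typical ~ -0.4)
    return [
        ("Saccharomyces", -0.39),
        ("Ambispora", -0.40),
        ("Dentiscutata", -0.43),
        ("Patellaria", -0.37),
        ("Acaromyces", -0.34),
        ("Cenococcum", -0.40),
    ]


@dataclass
class SyntheticSpec:
    """Full parameterisation of a simulated two-group cohort.

    Defaults describe the modelled study: 19 cases vs 17 controls, genus
    level, zero-inflated lognormal margins (sigma = 1), two depleted fungal
    genera, six fungi inversely rank-coupled to total IgE, and total IgE of
    285.6 +/- 102.4 IU/mL in cases vs 65.3 +/- 28.7 in controls.

    ``planted_edges`` maps a group label to the bacterium-fungus couplings
    active in that group's latent correlation matrix; taxa not named there
    are latently independent.
    """

    n_per_group: dict = field(default_factory=lambda: {CASE: 19, CONTROL: 17})
    n_bacteria: int = 60
    n_fungi: int = 60
    planted_edges: dict = field(default_factory=dict)
    depleted_taxa: list = field(default_factory=_default_depleted)
    zero_inflation: float = 0.3
    lognormal_sigma: float = 1.0
    ige_coupling: list = field(default_factory=_default_ige_coupling)
    ige_mean_sd: dict = field(
        default_factory=lambda: {CASE: (285.6, 102.4), CONTROL: (65.3, 28.7)}
    )
    inflate_planted: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 3:
                raise ValueError(f"group {g!r} needs >= 3 samples, got {n}")
        for g, edges in self.planted_edges.items():
            for e in edges:
                if not isinstance(e, PlantedEdge):
                    raise TypeError("planted_edges entries must be PlantedEdge")
        for t, rho in self.ige_coupling:
            if not (0 < abs(rho) < 1):
                raise ValueError(f"IgE coupling for {t!r} must be in (-1,1)\\0")
        for t, a, b in self.depleted_taxa:
            if not (0 < a < 1 and 0 < b < 1):
                raise ValueError(f"depleted fractions for {t!r} must be in (0,1)")
        if not (0 <= self.zero_inflation < 1):
            raise ValueError("zero_inflation must be in [0, 1)")
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be > 0")

    # -- taxon naming ---------------------------------------------------
    @property
    def bacteria(self) -> list:
        named = list(FOCAL_BACTERIA[: self.n_bacteria])
        extra = [f"Bacterium_{i:03d}" for i in range(len(named) + 1, self.n_bacteria + 1)]
        return named + extra

    @property
    def fungi(self) -> list:
        named = list(FOCAL_FUNGI[: self.n_fungi])
        extra = [f"Fungus_{i:03d}" for i in range(len(named) + 1, self.n_fungi + 1)]
        return named + extra

    @property
    def taxa(self) -> list:
        return self.bacteria + self.fungi

    def validate_taxa(self) -> None:
        known = set(self.taxa)
        bact, fung = set(self.bacteria), set(self.fungi)
        for g, edges in self.planted_edges.items():
            if g not in self.n_per_group:
                raise ValueError(f"planted_edges group {g!r} not in n_per_group")
            for e in edges:
                if e.bacterial_taxon not in bact:
                    raise ValueError(f"unknown bacterial taxon {e.bacterial_taxon!r}")
                if e.fungal_taxon not in fung:
                    raise ValueError(f"unknown fungal taxon {e.fungal_taxon!r}")
        for t, _ in self.ige_coupling:
            if t not in known:
                raise ValueError(f"unknown IgE-coupled taxon {t!r}")
        for t, _, _ in self.depleted_taxa:
            if t not in known:
                raise ValueError(f"unknown depleted taxon {t!r}")


def default_cohort_spec(seed: int = 0) -> SyntheticSpec:
    """Study-shaped default: a control network rich in negative couplings
    (44 negative + 7 positive) and a case network that is exclusively
    positive (17 couplings), all at |Spearman| = 0.8, on disjoint pairs.
    """
    spec = SyntheticSpec(seed=seed)
    bact, fung = spec.bacteria, spec.fungi
    # Planted pairs avoid the IgE-coupled focal fungi: those six already sit
    # in a latent star around the IgE node (sum of squared loadings ~ 0.98),
    # so any additional coupling on them would break positive definiteness.
    used_b, used_f = 5, 9
    hc = [PlantedEdge(bact[used_b + i], fung[used_f + i], -0.8)
          for i in range(44)]
    hc += [PlantedEdge(bact[used_b + i], fung[used_f + i], 0.8)
           for i in range(44, 51)]
    arfc = [PlantedEdge(bact[used_b + i], fung[used_f + i], 0.8)
            for i in range(17)]
    spec.planted_edges = {CONTROL: hc, CASE: arfc}
    spec.validate_taxa()
    return spec


def case_regime_spec(seed: int, n_samples: int = 19, n_edges: int = 17,
                     rho_s: float = 0.8, n_background: int = 20) -> SyntheticSpec:
    """A case-group-only cohort in the "co-dysbiosis" regime: ``n_edges``
    exclusively positive bacterium-fungus couplings (target Spearman
    ``rho_s``) plus ``n_background`` bacterial and fungal genera with no
    planted structure.  Planted taxa are exempt from zero inflation."""
    spec = SyntheticSpec(
        n_per_group={CASE: n_samples},
        n_bacteria=n_edges + n_background,
        n_fungi=n_edges + n_background,
        depleted_taxa=[], ige_coupling=[], seed=seed,
    )
    b, f = spec.bacteria, spec.fungi
    spec.planted_edges = {CASE: [PlantedEdge(b[i], f[i], rho_s)
                                 for i in range(n_edges)]}
    spec.validate_taxa()
    return spec


def control_regime_spec(seed: int, n_samples: int = 17,
                        n_negative: int = 44, n_positive: int = 7,
                        rho_s: float = 0.8, n_background: int = 10
                        ) -> SyntheticSpec:
    """A control-group-only cohort in the antagonism-rich regime:
    ``n_negative`` negative and ``n_positive`` positive couplings at
    |Spearman| = ``rho_s``."""
    n_edges = n_negative + n_positive
    spec = SyntheticSpec(
        n_per_group={CONTROL: n_samples},
        n_bacteria=n_edges + n_background,
        n_fungi=n_edges + n_background,
        depleted_taxa=[], ige_coupling=[], seed=seed,
        ige_mean_sd={CONTROL: (65.3, 28.7)},
    )
    b, f = spec.bacteria, spec.fungi
    edges = [PlantedEdge(b[i], f[i], -rho_s) for i in range(n_negative)]
    edges += [PlantedEdge(b[n_negative + i], f[n_negative + i], rho_s)
              for i in range(n_positive)]
    spec.planted_edges = {CONTROL: edges}
    spec.validate_taxa()
    return spec


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _latent_correlation(spec: SyntheticSpec, group: str) -> np.ndarray:
    """Correlation matrix over [taxa..., total IgE] for one group."""
    taxa = spec.taxa
    idx = {t: i for i, t in enumerate(taxa)}
    p = len(taxa) + 1  # last latent dimension is total IgE
    corr = np.eye(p)
    for e in spec.planted_edges.get(group, []):
        r = spearman_to_pearson(e.target_spearman)
        i, j = idx[e.bacterial_taxon], idx[e.fungal_taxon]
        corr[i, j] = corr[j, i] = r
    for t, rho in spec.ige_coupling:
        r = spearman_to_pearson(rho)
        corr[idx[t], p - 1] = corr[p - 1, idx[t]] = r
    return corr


def _cholesky_or_raise(corr: np.ndarray, group: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"latent correlation matrix for group {group!r} is not positive "
            "definite; plant fewer or weaker couplings (taxa sharing a node "
            "constrain each other)"
        ) from exc


def _geometric_means(n: int, total: float, decades: float = 1.0) -> np.ndarray:
    """Mildly uneven base means: geometric decay over ``decades`` orders of
    magnitude, scaled to sum to ``total``."""
    if n == 0:
        return np.zeros(0)
    w = 10.0 ** (-decades * np.arange(n) / max(n - 1, 1))
    return total * w / w.sum()


def _base_means(spec: SyntheticSpec, group: str) -> pd.Series:
    """Expected relative fraction of each taxon within its kingdom.

    Pinned fractions (depleted taxa and IgE-coupled focal fungi) are targets
    on the *realized* community, so the remaining mass assigned to
    zero-inflatable background taxa is scaled up by 1/(1 - zero_inflation):
    in expectation the kingdom total is 1 and each pinned taxon's mean
    fraction equals its target.
    """
    means = pd.Series(0.0, index=spec.taxa)
    depleted = {t: (hc, arfc) for t, hc, arfc in spec.depleted_taxa}
    pinned_f, pinned_b = {}, {}
    for t, (hc, arfc) in depleted.items():
        target = arfc if group == CASE else hc
        (pinned_f if t in set(spec.fungi) else pinned_b)[t] = target
    # focal fungi that are IgE-coupled but not depleted get a visible mean
    for t, _ in spec.ige_coupling:
        if t in set(spec.fungi) and t not in pinned_f:
            pinned_f[t] = 0.01
    protected = _protected_taxa(spec, group)
    for kingdom, pinned in (("bacteria", pinned_b), ("fungi", pinned_f)):
        taxa = spec.bacteria if kingdom == "bacteria" else spec.fungi
        rest = [t for t in taxa if t not in pinned]
        for t, v in pinned.items():
            means[t] = v
        remaining = 1.0 - sum(pinned.values())
        if remaining <= 0:
            raise ValueError(f"pinned {kingdom} fractions exceed 1")
        means[rest] = _geometric_means(len(rest), remaining)
        # compensate the expected mass lost to structural zeros
        inflatable = [t for t in rest if t not in protected]
        lost = spec.zero_inflation * means[inflatable].sum()
        surviving = means[rest].sum() - lost
        if surviving > 0 and lost > 0:
            means[rest] *= remaining / surviving
    return means


def _lognormal_params(mean: float, sd: float):
    """(mu, sigma) of a lognormal with the given mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("lognormal moment matching needs mean, sd > 0")
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _protected_taxa(spec: SyntheticSpec, group: str) -> set:
    """Taxa exempt from zero inflation (so planted couplings and pinned
    means are not eroded by structural zeros)."""
    if spec.inflate_planted:
        return set()
    prot = {t for t, _, _ in spec.depleted_taxa}
    prot |= {t for t, _ in spec.ige_coupling}
    for e in spec.planted_edges.get(group, []):
        prot |= {e.bacterial_taxon, e.fungal_taxon}
    return prot


def simulate_group(spec: SyntheticSpec, group: str, n: int, rng) -> dict:
    """Simulate one group; returns the intermediate stages.

    Keys: ``latent`` (n x (taxa+1) standard-normal draws under the group's
    latent correlation), ``raw`` (lognormal margins before zero inflation),
    ``inflated`` (after structural zeros), ``fractions`` (per-kingdom
    total-sum scaled), ``total_ige``.
    """
    taxa = spec.taxa
    corr = _latent_correlation(spec, group)
    L = _cholesky_or_raise(corr, group)
    z = rng.standard_normal((n, corr.shape[0])) @ L.T
    z_taxa, z_ige = z[:, :-1], z[:, -1]

    sig = spec.lognormal_sigma
    m = _base_means(spec, group).values
    # E[m * exp(sig z - sig^2/2)] = m
    raw = m * np.exp(sig * z_taxa - sig**2 / 2.0)

    inflated = raw.copy()
    if spec.zero_inflation > 0:
        mask = rng.random(raw.shape) < spec.zero_inflation
        prot = _protected_taxa(spec, group)
        for j, t in enumerate(taxa):
            if t in prot:
                mask[:, j] = False
        inflated[mask] = 0.0

    fractions = inflated.copy()
    for kingdom_taxa in (spec.bacteria, spec.fungi):
        cols = [taxa.index(t) for t in kingdom_taxa]
        tot = fractions[:, cols].sum(axis=1, keepdims=True)
        tot[tot == 0] = np.inf
        fractions[:, cols] = fractions[:, cols] / tot

    mu, s = _lognormal_params(*spec.ige_mean_sd[group])
    total_ige = np.exp(mu + s * z_ige)
    return {
        "latent": z_taxa,
        "latent_ige": z_ige,
        "raw": raw,
        "inflated": inflated,
        "fractions": fractions,
        "total_ige": total_ige,
    }


_TABLE1 = {
    # group -> (age mean, sd), (height mean, sd), (weight mean, sd), male frac
    CASE: ((4.8, 0.9), (105.3, 6.2), (18.2, 2.4), 10 / 19),
    CONTROL: ((4.5, 1.1), (107.1, 5.8), (17.8, 2.1), 9 / 17),
}

# allergen -> (case mean, case sd, control mean, control sd) in kU_A/L
_ALLERGENS = {
    "house_dust_mite": (3.0, 2.5, 0.20, 0.15),
    "shrimp": (1.0, 1.2, 0.10, 0.10),
    "crab": (0.9, 1.0, 0.10, 0.10),
    "egg": (0.8, 0.9, 0.15, 0.12),
}


def _metadata_for_group(spec, group, n, sim, rng) -> pd.DataFrame:
    (age_m, age_s), (h_m, h_s), (w_m, w_s), male = _TABLE1.get(
        group, ((4.6, 1.0), (106.0, 6.0), (18.0, 2.2), 0.5)
    )
    frame = pd.DataFrame(index=[f"{group}{i + 1:02d}" for i in range(n)])
    frame["group"] = group
    frame["age"] = np.round(np.clip(rng.normal(age_m, age_s, n), 3.0, 6.0), 1)
    frame["sex"] = np.where(rng.random(n) < male, "M", "F")
    frame["height_cm"] = np.round(rng.normal(h_m, h_s, n), 1)
    frame["weight_kg"] = np.round(rng.normal(w_m, w_s, n), 1)
    frame["total_ige"] = sim["total_ige"]
    z_ige = sim["latent_ige"]
    for allergen, vals in _ALLERGENS.items():
        m, s = (vals[0], vals[1]) if group == CASE else (vals[2], vals[3])
        mu, sg = _lognormal_params(m, s)
        # latent correlated with the total-IgE latent: allergen-specific IgE
        # co-varies with total IgE within a child
        lat = 0.6 * z_ige + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        frame[f"sIgE_{allergen}"] = np.exp(mu + sg * lat)
    return frame


def simulate_cohort(spec: SyntheticSpec):
    """Draw one cohort; returns ``(AbundanceTable, SampleMetadata)``.

    Fully reproducible from ``spec.seed``: the same spec yields identical
    outputs.  The abundance table holds per-kingdom relative fractions
    (``normalized=True``).
    """
    spec.validate_taxa()
    rng = np.random.default_rng(spec.seed)
    taxa = spec.taxa
    kingdom = pd.Series(
        ["bacteria"] * len(spec.bacteria) + ["fungi"] * len(spec.fungi),
        index=taxa,
    )
    rank = pd.Series("genus", index=taxa)

    blocks, metas = [], []
    for group in sorted(spec.n_per_group):
        n = spec.n_per_group[group]
        sim = simulate_group(spec, group, n, rng)
        meta = _metadata_for_group(spec, group, n, sim, rng)
        blocks.append(pd.DataFrame(sim["fractions"], index=meta.index, columns=taxa))
        metas.append(meta)

    table = AbundanceTable(pd.concat(blocks), kingdom, rank,
                           normalized=True, norm_mode="per_kingdom")
    metadata = SampleMetadata(pd.concat(metas))
    return table, metadata


def simulate_ko_dataset(n_ko: int = 200, n_pathways: int = 20,
                        ko_per_pathway: int = 10, n_shifted_pathways: int = 0,
                        shift_size: float = 0.0, groups: dict | None = None,
                        sigma: float = 1.0, seed: int = 0):
    """Simulate a KO (gene-family) abundance table and a KO->pathway map.

    KO abundances are lognormal with per-KO location drawn once; members of
    the first ``n_shifted_pathways`` pathways receive a ``shift_size``-SD
    group-mean shift (up in the case group).  With ``shift_size=0`` the two
    groups are exchangeable.  Returns ``(ko_table, pathway_map)`` where
    ``ko_table`` is samples x KOs (sample ids prefixed by group label) and
    ``pathway_map`` has columns pathway_id, level1, level2, level3, ko_id.
    """
    if groups is None:
        groups = {CASE: 19, CONTROL: 17}
    if n_shifted_pathways > n_pathways:
        raise ValueError("n_shifted_pathways must be <= n_pathways")
    if n_pathways * ko_per_pathway > n_ko:
        raise ValueError("not enough KOs to fill the requested pathways")
    rng = np.random.default_rng(seed)
    kos = [f"K{i:05d}" for i in range(1, n_ko + 1)]
    mu = rng.normal(0.0, 1.0, n_ko)

    rows = []
    for p in range(n_pathways):
        members = kos[p * ko_per_pathway:(p + 1) * ko_per_pathway]
        for ko in members:
            rows.append((f"map{p + 1:05d}", "Metabolism",
                         f"Level2_{p % 5 + 1}", f"Pathway_{p + 1}", ko))
    pathway_map = pd.DataFrame(
        rows, columns=["pathway_id", "level1", "level2", "level3", "ko_id"]
    )
    shifted = set()
    for p in range(n_shifted_pathways):
        shifted.update(kos[p * ko_per_pathway:(p + 1) * ko_per_pathway])

    blocks = []
    for group in sorted(groups):
        n = groups[group]
        loc = mu.copy()
        if group == CASE and shifted:
            loc = loc + shift_size * sigma * np.isin(kos, list(shifted))
        z = rng.standard_normal((n, n_ko))
        vals = np.exp(loc + sigma * z)
        blocks.append(pd.DataFrame(
            vals, index=[f"{group}{i + 1:02d}" for i in range(n)], columns=kos
        ))
    return pd.concat(blocks), pathway_map
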
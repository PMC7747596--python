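"""Synthetic anther-lipidome studies with known ground truth.

The generator emulates the structure the downstream analyses assume: a
two-year field trial (2 years x 2 blocks x 4 replications) of several peanut
genotypes under ambient (AT) and heat (HT) treatments, profiled for 89 lipid
analytes across 12 headgroup classes, plus quality-control pool injections
and a qRT-PCR cycle-threshold table for the FAD desaturase genes.

Generated values are multiplicative:

    signal = baseline * heat multiplier (genotype-specific)
             * year shift * block shift * latent group factor * lognormal noise

The heat effect depletes every 18:3-containing species by a genotype-specific
factor and inflates every TAG species by a genotype-specific gain, mirroring
heat-driven membrane-lipid remodeling.  Designated co-occurring lipid groups
share a per-sample latent lognormal factor, so they rise and fall together
across samples (coordinated metabolism); the planted group labels, per-analyte
heat multipliers, and true expression fold changes are returned as ground
truth for recovery tests.

All randomness is drawn from named substreams of a master seed, so adding
analytes or samples does not perturb unrelated draws and a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import LipidDataset, Unit
from .nomenclature import (
    AcylChain,
    Headgroup,
    contains_fatty_acid,
    parse_lipid_name,
)

FA_18_3 = AcylChain(18, 3)

# ---------------------------------------------------------------------------
# Baseline template: 89 analytes, percent of total signal under AT.
# Class shares: PC 44, PE 18, TAG 9, PI 3, PA 2, PG 2.5, MGDG 2, SQDG 1.5,
# DAG 2, ASG 5, SG 4, SE 7 (sums to 100). Within the diacyl "structural
# glycerolipid" classes the pooled 34:3 / 34:2 / 36:6 / 36:5 / 36:4 species
# make up 26.0 / 25.9 / 11.4 / 15.7 / 12.8 percent of the structural total.
# ---------------------------------------------------------------------------

_TEMPLATE: tuple[tuple[str, float], ...] = (
    # PC (10 species, 44.0)
    ("PC(34:4)", 0.5), ("PC(34:3)", 12.0), ("PC(34:2)", 11.0), ("PC(34:1)", 1.0),
    ("PC(36:6)", 5.0), ("PC(36:5)", 8.0), ("PC(36:4)", 5.0), ("PC(36:3)", 0.8),
    ("PC(36:2)", 0.4), ("PC(36:1)", 0.3),
    # PE (8 species, 18.0)
    ("PE(34:3)", 4.5), ("PE(34:2)", 4.5), ("PE(34:1)", 0.6), ("PE(36:6)", 2.2),
    ("PE(36:5)", 2.8), ("PE(36:4)", 2.6), ("PE(36:3)", 0.5), ("PE(36:2)", 0.3),
    # PI (6 species, 3.0)
    ("PI(34:3)", 0.8), ("PI(34:2)", 1.0), ("PI(34:1)", 0.3), ("PI(36:6)", 0.1),
    ("PI(36:5)", 0.3), ("PI(36:4)", 0.5),
    # PA (4 species, 2.0)
    ("PA(34:3)", 0.5), ("PA(34:2)", 0.7), ("PA(36:5)", 0.3), ("PA(36:4)", 0.5),
    # PG (4 species, 2.5)
    ("PG(34:3)", 0.6), ("PG(34:2)", 1.0), ("PG(34:1)", 0.5), ("PG(36:4)", 0.4),
    # MGDG (4 species, 2.0)
    ("MGDG(36:6)", 1.0), ("MGDG(36:5)", 0.4), ("MGDG(36:4)", 0.3), ("MGDG(34:3)", 0.3),
    # SQDG (4 species, 1.5)
    ("SQDG(34:3)", 0.3), ("SQDG(34:2)", 0.6), ("SQDG(34:1)", 0.35), ("SQDG(36:6)", 0.25),
    # DAG (5 species, 2.0)
    ("DAG(34:3)", 0.5), ("DAG(34:2)", 0.6), ("DAG(36:3)_A", 0.3), ("DAG(36:3)_B", 0.3),
    ("DAG(36:4)", 0.3),
    # TAG (26 species, 9.0)
    ("TAG(16:0/16:0/16:0)", 0.40), ("TAG(18:1/16:0/16:0)", 0.30),
    ("TAG(18:2/16:0/16:0)", 0.55), ("TAG(18:3/16:0/16:0)", 0.35),
    ("TAG(18:0/16:0/18:1)", 0.20), ("TAG(18:1/16:0/18:1)", 0.45),
    ("TAG(18:2/16:0/18:1)", 0.70), ("TAG(52:4)_A", 0.50),
    ("TAG(52:4)_B", 0.50), ("TAG(16:0/18:3/18:2)", 0.45),
    ("TAG(16:0/18:3/18:3)", 0.30), ("TAG(18:1/18:1/18:1)", 0.35),
    ("TAG(18:1/18:2/18:1)", 0.50), ("TAG(54:5)", 0.25),
    ("TAG(18:1/18:3/18:2)", 0.50), ("TAG(18:2/18:2/18:2)", 0.35),
    ("TAG(54:7)_A", 0.50), ("TAG(54:7)_B", 0.35),
    ("TAG(18:3/18:3/18:2)", 0.25), ("TAG(18:3/18:3/18:3)", 0.20),
    ("TAG(18:0/16:0/16:0)", 0.15), ("TAG(16:0/16:1/18:2)", 0.20),
    ("TAG(18:0/18:2/16:0)", 0.25), ("TAG(16:0/16:1/18:1)", 0.20),
    ("TAG(18:0/18:1/18:1)", 0.15), ("TAG(18:0/18:2/18:1)", 0.10),
    # ASG (8 species, 5.0)
    ("ASG(16:0)", 1.2), ("ASG(18:0)", 0.5), ("ASG(18:1)", 1.0), ("ASG(18:2)", 1.3),
    ("ASG(18:3)", 0.6), ("ASG(20:0)", 0.2), ("ASG(22:0)", 0.1), ("ASG(16:1)", 0.1),
    # SG (1 analyte, 4.0)
    ("SG", 4.0),
    # SE (9 species, 7.0)
    ("SE(16:0)", 1.5), ("SE(18:0)", 0.6), ("SE(18:1)", 1.6), ("SE(18:2)", 1.8),
    ("SE(18:3)", 0.7), ("SE(16:1)", 0.2), ("SE(20:0)", 0.3), ("SE(20:1)", 0.2),
    ("SE(22:0)", 0.1),
)

#: Planted co-occurring lipid groups (shared latent factor).  Members of the
#: "down" groups that do not themselves carry an 18:3 chain still deplete
#: under heat (at the square root of the genotype factor): their response is
#: coordinated by the shared headgroup rather than by acyl content.
DEFAULT_BLOCKS: dict[str, tuple[str, ...]] = {
    "PC_18:3": ("PC(34:3)", "PC(36:5)", "PC(36:6)"),
    "PE": ("PE(34:3)", "PE(34:2)", "PE(36:6)", "PE(36:5)", "PE(36:4)"),
    "TAG_A": (
        "TAG(18:2/16:0/18:1)", "TAG(52:4)_B", "TAG(16:0/18:3/18:2)",
        "TAG(18:2/16:0/16:0)", "TAG(18:1/16:0/18:1)", "TAG(18:1/16:0/16:0)",
    ),
    "TAG_B": (
        "TAG(18:1/18:2/18:1)", "TAG(18:1/18:3/18:2)", "TAG(54:7)_A",
        "TAG(54:7)_B", "TAG(18:2/18:2/18:2)", "TAG(18:1/18:1/18:1)",
    ),
}


def default_template() -> pd.Series:
    """Baseline AT composition (percent of total signal) for the 89 analytes."""
    s = pd.Series(dict(_TEMPLATE), name="baseline_percent", dtype=float)
    return s


@dataclass(frozen=True)
class GenotypeEffect:
    """Per-genotype heat response: multiplier on 18:3-containing species
    (depletion, < 1) and on TAG species (gain, > 1); ``years`` restricts the
    genotype to a subset of trial years (None = all)."""

    name: str
    depletion_18_3: float
    tag_gain: float
    years: Optional[tuple[int, ...]] = None

    def __post_init__(self):
        if self.depletion_18_3 <= 0 or self.tag_gain <= 0:
            raise ValueError(f"{self.name}: multipliers must be positive")


#: Default genotype panel. Heat-tolerant genotypes deplete 18:3 species more
#: strongly and accumulate more TAG; Sugg was grown only in the first year and
#: SPT 06-07 only in the second.
DEFAULT_GENOTYPES: tuple[GenotypeEffect, ...] = (
    GenotypeEffect("Bailey", 0.90, 1.8),
    GenotypeEffect("Wynne", 0.80, 2.2),
    GenotypeEffect("Georgia 12Y", 0.70, 2.8),
    GenotypeEffect("Tifguard", 0.75, 2.5),
    GenotypeEffect("Phillips", 0.80, 2.3),
    GenotypeEffect("Sugg", 0.80, 2.2, years=(2018,)),
    GenotypeEffect("SPT 06-07", 0.60, 3.2, years=(2019,)),
)

#: True expression fold changes (HT/AT, 2^-ddCT scale) per genotype x gene.
DEFAULT_GENE_FOLDS: dict[tuple[str, str], float] = {
    ("Wynne", "FAD2-1"): 2.8,
    ("Georgia 12Y", "FAD2-1"): 3.2,
    ("Tifguard", "FAD2-1"): 3.9,
    ("Bailey", "FAD2-2"): 3.9,
    ("Georgia 12Y", "FAD3-2"): 1.8,
    ("SPT 06-07", "FAD3-2"): 1.0 / 1.7,
}

GENES = ("FAD2-1", "FAD2-2", "FAD3-1", "FAD3-2")
REFERENCE_GENE = "Actin-7"


@dataclass
class SimConfig:
    """Study-generator configuration (defaults are the emulated trial)."""

    genotypes: tuple[GenotypeEffect, ...] = DEFAULT_GENOTYPES
    years: tuple[int, ...] = (2018, 2019)
    blocks_per_year: int = 2
    reps: int = 4
    template: Optional[pd.Series] = None     # baseline percent; None = default
    blocks: Optional[dict[str, tuple[str, ...]]] = None  # co-occurrence groups
    total_signal: float = 2.0                # total signal per mg dry weight
    noise_cv: float = 0.20                   # replicate CoV, ordinary analytes
    block_noise_cv: float = 0.06             # residual CoV of group members
    block_sigma: float = 0.35                # log-sd of the latent group factor
    year_sigma: float = 0.05                 # log-sd of year shifts
    block_shift_sigma: float = 0.05          # log-sd of block-within-year shifts
    qc_pool_n: int = 6                       # QC-pool injections per year
    qc_cv: float = 0.10                      # QC-pool replicate CoV
    n_junk_lod: int = 0                      # extra analytes planted below LOD
    n_junk_cov: int = 0                      # extra analytes with high QC CoV
    gene_folds: Optional[dict[tuple[str, str], float]] = None
    ct_bio_reps: int = 3
    ct_tech_reps: int = 2
    ct_bio_sd: float = 0.15                  # CT cycles, biological replicates
    ct_tech_sd: float = 0.05                 # CT cycles, technical replicates
    seed: int = 0

    def resolved_template(self) -> pd.Series:
        return default_template() if self.template is None else self.template.astype(float)

    def resolved_blocks(self) -> dict[str, tuple[str, ...]]:
        if self.blocks is not None:
            return self.blocks
        if self.template is not None:
            return {}
        return DEFAULT_BLOCKS

    def resolved_gene_folds(self) -> dict[tuple[str, str], float]:
        return DEFAULT_GENE_FOLDS if self.gene_folds is None else self.gene_folds


@dataclass
class SimTruth:
    """Ground truth of one simulated study."""

    baseline_percent: pd.Series                  # per analyte
    ht_multiplier: pd.DataFrame                  # genotype x analyte
    block_labels: pd.Series                      # analyte -> group name or ""
    junk_analytes: dict[str, str]                # analyte -> below_LOD | high_CoV
    gene_folds: dict[tuple[str, str], float]     # (genotype, gene) -> true fold

    @property
    def planted_responders(self) -> list[str]:
        changed = (self.ht_multiplier != 1.0).any(axis=0)
        return [a for a in changed.index[changed] if a not in self.junk_analytes]

    def to_json_dict(self) -> dict:
        return {
            "baseline_percent": self.baseline_percent.to_dict(),
            "ht_multiplier": {g: row.to_dict() for g, row in self.ht_multiplier.iterrows()},
            "block_labels": self.block_labels[self.block_labels != ""].to_dict(),
            "junk_analytes": self.junk_analytes,
            "gene_folds": {f"{g}|{gene}": v for (g, gene), v in self.gene_folds.items()},
        }


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream of the master seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _lognormal(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise."""
    if sigma == 0:
        return np.ones(size)
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size))


def _cv_to_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


_JUNK_POOL = (
    "PC(38:2)", "PE(38:3)", "PI(36:3)", "PA(36:3)", "PG(36:5)", "MGDG(34:2)",
    "SQDG(36:5)", "PC(38:3)", "PE(38:2)", "PI(36:1)",
)


def _contains_18_3(name: str) -> bool:
    sp = parse_lipid_name(name)
    if contains_fatty_acid(sp, FA_18_3):
        return True
    # diacyl species without an assignment: totals that necessarily carry an
    # 18:3 chain among the common C16/C18 fatty acids
    if sp.chains is None and sp.chain_count == 2:
        return (sp.total_carbons, sp.total_double_bonds) in {
            (34, 3), (34, 4), (36, 5), (36, 6), (36, 7)
        }
    return False


def simulate_study(config: SimConfig) -> tuple[LipidDataset, SimTruth]:
    """Generate a complete lipid study (experimental + QC-pool samples, signal
    units) together with its ground truth."""
    template = config.resolved_template()
    blocks = config.resolved_blocks()
    seed = config.seed

    analytes = list(template.index)
    junk: dict[str, str] = {}
    baselines = template / template.sum() * 100.0
    base_signal = baselines / 100.0 * config.total_signal

    for i in range(config.n_junk_lod):
        name = _JUNK_POOL[i % len(_JUNK_POOL)]
        junk[name] = "below_LOD"
        analytes.append(name)
        base_signal[name] = 0.00001  # below the default LOD
        baselines[name] = 0.0
    for i in range(config.n_junk_cov):
        name = _JUNK_POOL[(config.n_junk_lod + i) % len(_JUNK_POOL)]
        if name in junk:
            raise ValueError("junk analyte pool exhausted; reduce junk counts")
        junk[name] = "high_CoV"
        analytes.append(name)
        base_signal[name] = 0.02 * config.total_signal
        baselines[name] = 0.0

    block_of = pd.Series("", index=analytes, dtype=object)
    for label, members in blocks.items():
        for m in members:
            if m not in block_of.index:
                raise ValueError(f"block {label}: analyte {m!r} not in template")
            block_of[m] = label

    species = {a: parse_lipid_name(a) for a in analytes}
    is_tag = {a: species[a].headgroup is Headgroup.TAG for a in analytes}
    has_18_3 = {a: _contains_18_3(a) for a in analytes}

    # a block is a "down" group if any member carries 18:3 and none is TAG
    down_blocks = {
        lbl for lbl, members in blocks.items()
        if any(has_18_3[m] for m in members) and not any(is_tag[m] for m in members)
    }
    mult = pd.DataFrame(
        1.0, index=[g.name for g in config.genotypes], columns=analytes
    )
    for g in config.genotypes:
        for a in analytes:
            if a in junk:
                continue
            if is_tag[a]:
                mult.loc[g.name, a] = g.tag_gain
            elif has_18_3[a]:
                mult.loc[g.name, a] = g.depletion_18_3
            elif block_of[a] in down_blocks:
                # headgroup-coordinated partial depletion
                mult.loc[g.name, a] = float(np.sqrt(g.depletion_18_3))

    # per-year and per-block multiplicative shifts (shared by all analytes)
    rng_year = _rng(seed, "year_shifts")
    year_shift = {y: float(_lognormal(rng_year, config.year_sigma, ())) for y in config.years}
    rng_block = _rng(seed, "block_shifts")
    block_shift = {
        (y, b): float(_lognormal(rng_block, config.block_shift_sigma, ()))
        for y in config.years
        for b in range(1, config.blocks_per_year + 1)
    }

    sigma_noise = _cv_to_sigma(config.noise_cv)
    sigma_block_member = _cv_to_sigma(config.block_noise_cv)

    rows, meta_rows = [], []
    rng_latent = _rng(seed, "latent_blocks")
    rng_noise = _rng(seed, "replicate_noise")
    block_names = sorted(blocks)
    n_analytes = len(analytes)
    resid_sigma = np.array(
        [sigma_block_member if block_of[a] else sigma_noise for a in analytes]
    )
    for year in config.years:
        for g in config.genotypes:
            if g.years is not None and year not in g.years:
                continue
            for treatment in ("AT", "HT"):
                tmult = (
                    mult.loc[g.name].to_numpy()
                    if treatment == "HT"
                    else np.ones(n_analytes)
                )
                for block in range(1, config.blocks_per_year + 1):
                    for rep in range(1, config.reps + 1):
                        latent = {
                            lbl: float(_lognormal(rng_latent, config.block_sigma, ()))
                            for lbl in block_names
                        }
                        lat = np.array(
                            [latent[block_of[a]] if block_of[a] else 1.0 for a in analytes]
                        )
                        noise = np.exp(
                            rng_noise.normal(-0.5 * resid_sigma**2, resid_sigma)
                        )
                        vals = (
                            base_signal[analytes].to_numpy()
                            * tmult
                            * year_shift[year]
                            * block_shift[(year, block)]
                            * lat
                            * noise
                        )
                        sid = f"Y{year}_B{block}_R{rep}_{g.name.replace(' ', '')}_{treatment}"
                        rows.append(vals)
                        meta_rows.append(
                            {"sample_id": sid, "genotype": g.name,
                             "treatment": treatment, "year": year, "block": block,
                             "replicate": rep, "is_qc_pool": False}
                        )

    # QC-pool injections: drawn around the grand baseline
    rng_qc = _rng(seed, "qc_pool")
    sigma_qc = _cv_to_sigma(config.qc_cv)
    qc_cov_sigma = _cv_to_sigma(0.6)  # planted-to-fail CoV
    for year in config.years:
        for k in range(1, config.qc_pool_n + 1):
            per_sigma = np.array(
                [qc_cov_sigma if junk.get(a) == "high_CoV" else sigma_qc for a in analytes]
            )
            vals = base_signal[analytes].to_numpy() * np.exp(
                rng_qc.normal(-0.5 * per_sigma**2, per_sigma)
            )
            sid = f"Y{year}_QC{k}"
            rows.append(vals)
            meta_rows.append(
                {"sample_id": sid, "genotype": "pool", "treatment": "pool",
                 "year": year, "block": 0, "replicate": k, "is_qc_pool": True}
            )

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    values = pd.DataFrame(rows, index=meta.index, columns=analytes)
    ds = LipidDataset(values, meta, Unit.SIGNAL)
    truth = SimTruth(
        baseline_percent=baselines[analytes],
        ht_multiplier=mult,
        block_labels=block_of,
        junk_analytes=junk,
        gene_folds=config.resolved_gene_folds(),
    )
    return ds, truth


def simulate_ct_table(config: SimConfig) -> pd.DataFrame:
    """Generate a qRT-PCR CT table whose ddCT analysis recovers the configured
    true fold changes (genes vs the Actin-7 reference)."""
    folds = config.resolved_gene_folds()
    rng = _rng(config.seed, "ct_table")
    base_ct = {REFERENCE_GENE: 20.0}
    for i, gene in enumerate(GENES):
        base_ct[gene] = 24.0 + 0.5 * i
    rows = []
    for g in config.genotypes:
        for treatment in ("AT", "HT"):
            for bio in range(1, config.ct_bio_reps + 1):
                bio_shift = rng.normal(0.0, config.ct_bio_sd)  # plate/sample shift
                for gene in (REFERENCE_GENE,) + GENES:
                    ct0 = base_ct[gene]
                    if treatment == "HT" and gene != REFERENCE_GENE:
                        fold = folds.get((g.name, gene), 1.0)
                        ct0 = ct0 - np.log2(fold)  # higher expression = lower CT
                    bio_noise = rng.normal(0.0, config.ct_bio_sd)
                    for tech in range(1, config.ct_tech_reps + 1):
                        ct = ct0 + bio_shift + bio_noise + rng.normal(0.0, config.ct_tech_sd)
                        rows.append(
                            {"genotype": g.name, "treatment": treatment,
                             "biological_rep": bio, "technical_rep": tech,
                             "gene": gene, "ct": ct}
                        )
    return pd.DataFrame(rows)
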
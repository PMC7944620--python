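"""Triad-structured synthetic count datasets with planted ground truth.

The generator emits exactly the input contracts the pipeline reads
(per-sample gene count TSVs, a triad table, gene coordinates, a zone
partition) together with the planted truth: per triad x genotype x
assay bias categories and, for three-genotype series, the planted
Group/Pattern transition label.  Counts are drawn negative-binomially
around length- and library-scaled expectations so that the expected
TPM of each gene equals its planted value; with ``noiseless=True``
expectations are emitted directly (rounded to integers), and planted
labels are then recoverable without error.

Default proportions encode the study conditions of the wheat analysis
this package implements: per-marker modified-triad fractions, balanced
vs A-/B-biased category proportions, and Group/Pattern transition
frequencies for the domestication (WTW -> DTW -> ETW) and ploidy
transition (TAA10 -> ETW -> XX329) series.  Planted counts follow a
largest-remainder rounding of n * proportion, so truth frequencies are
exact rather than sampled.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import CATEGORIES, UNMODIFIED
from .io import SUBGENOMES, TriadTable, validate_zones
from .tracking import LABELS

#: ploidy of the built-in genotypes; unknown genotypes are treated AABB
PLOIDY = {"WTW": "AABB", "DTW": "AABB", "ETW": "AABB",
          "TAA10": "AABBDD", "XX329": "AABBDD", "DD": "DD"}

#: fraction of triads modified by each assay (union-style planting:
#: a triad is modified in every genotype or in none)
DEFAULT_MODIFIED = {"H3K4me3": 0.814, "H3K27me3": 0.505, "RNA": 0.90}

#: (pi_eq, pi_gt, pi_lt) among modified triads, first/series-anchor genotype
DEFAULT_CATEGORY_PROPS = {
    "H3K4me3": (0.894, 0.068, 0.038),
    "H3K27me3": (0.849, 0.088, 0.063),
    "RNA": (0.805, 0.117, 0.078),
}

#: planted transition-class frequencies (I, II, III, IV) per series
DEFAULT_GROUP_FREQS = {
    "domestication": {
        "H3K4me3": (0.883, 0.048, 0.033, 0.036),
        "H3K27me3": (0.709, 0.108, 0.083, 0.100),
        "RNA": (0.800, 0.070, 0.060, 0.070),
    },
    "ploidy": {
        "H3K4me3": (0.961, 0.008, 0.008, 0.023),
        "H3K27me3": (0.767, 0.050, 0.050, 0.133),
        "RNA": (0.850, 0.050, 0.040, 0.060),
    },
}

#: negative-binomial dispersion per assay (var = m + m^2/phi), chosen so
#: replicate TPM correlations under the default signal spread emulate the
#: study's replicate concordance (r ~ 0.99 for H3K4me3, ~ 0.91 for H3K27me3)
DEFAULT_PHI = {"H3K4me3": 200.0, "H3K27me3": 12.0, "RNA": 40.0}

#: mean-signal multiplier by chromosomal compartment
DEFAULT_ZONE_WEIGHTS = {
    "H3K4me3": {"distal": 3.0, "interstitial": 2.0, "proximal": 1.0},
    "H3K27me3": {"distal": 2.0, "interstitial": 1.5, "proximal": 1.0},
    "RNA": {"distal": 1.0, "interstitial": 1.0, "proximal": 1.0},
}

#: chromosome partition used for the synthetic genome (fractions of
#: chromosome length): distal R1/R3, interstitial R2a/R2b, proximal C
ZONE_FRACTIONS = (("R1", 0.00, 0.15), ("R2a", 0.15, 0.45),
                  ("C", 0.45, 0.55), ("R2b", 0.55, 0.85),
                  ("R3", 0.85, 1.00))

_COMPARTMENT = {"R1": "distal", "R3": "distal", "R2a": "interstitial",
                "R2b": "interstitial", "C": "proximal"}

CHROM_LENGTH = 100_000_000
N_CHROM_GROUPS = 7


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_triads: int = 2000
    genotypes: tuple = ("WTW", "DTW", "ETW")
    assays: tuple = ("H3K4me3", "H3K27me3")
    replicates: int = 2
    seed: int = 0
    series: str | None = None          # "domestication" | "ploidy" | None
    mu: float = 50.0                   # per-gene TPM scale; triad total ~2*mu
    sigma_log: float = 1.0             # lognormal spread of triad signal
    epsilon: float = 0.2               # ceiling TPM of unmodified homoeologs
    tau: float = 0.5                   # threshold the analysis will apply
    min_modified_tpm: float = 20.0     # floor on a modified triad's A+B TPM
    noiseless: bool = False
    phi: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PHI))
    modified_props: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODIFIED))
    category_props: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPS))
    group_freqs: Mapping[str, tuple] | None = None
    expression_coupling: float = 0.5   # P(RNA label copies H3K4me3 label)
    rel_biased: tuple = (0.80, 0.95)   # rel of the favoured homoeolog
    rel_balanced: tuple = (0.45, 0.55)
    library_per_1k: float = 1e6

    def __post_init__(self) -> None:
        if self.n_triads < 1:
            raise ValueError("n_triads must be >= 1")
        if not (self.epsilon < self.tau < self.mu):
            raise ValueError("need epsilon < tau < mu")
        for assay, p in self.phi.items():
            if not p > 0:
                raise ValueError(f"phi[{assay}] must be > 0")
        for assay, props in self.category_props.items():
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError(f"category proportions for {assay} "
                                 "must sum to 1")
        if self.group_freqs is not None:
            for assay, freqs in self.group_freqs.items():
                if len(freqs) != 4:
                    raise ValueError("group frequency vector must have "
                                     "4 entries (I, II, III, IV)")
                if abs(sum(freqs) - 1.0) > 1e-9:
                    raise ValueError(f"group frequencies for {assay} "
                                     "must sum to 1")

    def library_size(self) -> int:
        return int(self.library_per_1k * max(self.n_triads, 1000) / 1000)


def largest_remainder(n: int, props) -> np.ndarray:
    """Integer counts summing to n: floor(n*p) plus remainders by
    largest fractional part (ties broken by position)."""
    props = np.asarray(props, dtype=float)
    exact = n * props
    base = np.floor(exact).astype(int)
    short = n - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:short]] += 1
    return base


@dataclass
class SimulatedDataset:
    """A generated dataset plus its recoverable ground truth."""

    config: SimConfig
    counts: dict                    # (genotype, assay, replicate) -> Series
    triads: TriadTable
    zones: pd.DataFrame
    truth_categories: pd.DataFrame  # triad_id, genotype, assay, category
    truth_labels: pd.DataFrame      # triad_id, assay, series, label
    design: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for (genotype, assay, rep), counts in sorted(self.counts.items()):
            df = counts.rename("count").rename_axis("gene_id").reset_index()
            df.to_csv(outdir / f"counts_{genotype}_{assay}_rep{rep}.tsv",
                      sep="\t", index=False)
        self.triads.table.reset_index().to_csv(
            outdir / "triads.tsv", sep="\t", index=False)
        coords = self.triads.coords.reset_index()
        coords[["chrom", "start", "end", "gene_id"]].to_csv(
            outdir / "genes.bed", sep="\t", index=False, header=False)
        self.zones.to_csv(outdir / "zones.tsv", sep="\t", index=False,
                          header=False)
        self.truth_categories.to_csv(outdir / "truth_categories.tsv",
                                     sep="\t", index=False)
        self.truth_labels.to_csv(outdir / "truth_labels.tsv",
                                 sep="\t", index=False)
        self.design.to_csv(outdir / "design.tsv", sep="\t", index=False)

    def checksum(self) -> str:
        """SHA-256 over all emitted tables (write + hash, in-memory)."""
        h = hashlib.sha256()
        for key, counts in sorted(self.counts.items()):
            h.update(str(key).encode())
            h.update(counts.to_csv(sep="\t").encode())
        for df in (self.triads.table, self.triads.coords, self.zones,
                   self.truth_categories, self.truth_labels, self.design):
            h.update(df.to_csv(sep="\t").encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# scaffold: triads, coordinates, zones
# ---------------------------------------------------------------------------

def _scaffold(cfg: SimConfig, rng: np.random.Generator):
    n = cfg.n_triads
    triad_ids = np.array([f"T{i:06d}" for i in range(n)])
    group = rng.integers(1, N_CHROM_GROUPS + 1, size=n)
    u = rng.uniform(0.0, 1.0, size=n)      # shared relative position
    coords_rows = []
    gene_ids = {}
    for sub in SUBGENOMES:
        lengths = rng.integers(1000, 5001, size=n)
        start = np.floor(u * (CHROM_LENGTH - lengths)).astype(int)
        ids = np.array([f"G{i:06d}_{sub}" for i in range(n)])
        gene_ids[sub] = ids
        for i in range(n):
            coords_rows.append((ids[i], f"chr{group[i]}{sub}",
                                start[i], start[i] + lengths[i]))
    coords = pd.DataFrame(coords_rows,
                          columns=["gene_id", "chrom", "start", "end"]
                          ).set_index("gene_id")
    coords["length"] = coords["end"] - coords["start"]
    table = pd.DataFrame({"gene_A": gene_ids["A"], "gene_B": gene_ids["B"],
                          "gene_D": gene_ids["D"]},
                         index=pd.Index(triad_ids, name="triad_id"))
    triads = TriadTable(table, coords)

    zone_rows = []
    for g in range(1, N_CHROM_GROUPS + 1):
        for sub in SUBGENOMES:
            for zone, lo, hi in ZONE_FRACTIONS:
                zone_rows.append((f"chr{g}{sub}", int(lo * CHROM_LENGTH),
                                  int(hi * CHROM_LENGTH), zone))
    zones = validate_zones(pd.DataFrame(
        zone_rows, columns=["chrom", "start", "end", "zone"]))

    compartment = np.empty(n, dtype=object)
    for zone, lo, hi in ZONE_FRACTIONS:
        mask = (u >= lo) & (u < hi)
        compartment[mask] = _COMPARTMENT[zone]
    compartment[u >= ZONE_FRACTIONS[-1][2]] = "distal"
    return triad_ids, triads, zones, compartment


# ---------------------------------------------------------------------------
# planting categories and series labels
# ---------------------------------------------------------------------------

def _other_category(rng: np.random.Generator, cat: str) -> str:
    options = [c for c in CATEGORIES if c != cat]
    return options[rng.integers(0, 2)]


def _series_triple(rng: np.random.Generator, label: str, c1: str,
                   series: str) -> tuple[str, str, str]:
    """A category triple realising the requested transition label."""
    if label == "I":
        return c1, c1, c1
    if series == "domestication":
        if label == "II":
            c2 = _other_category(rng, c1)
            return c1, c2, c2
        if label == "III":
            c2 = _other_category(rng, c1)
            return c1, c2, _other_category(rng, c2)
        c3 = _other_category(rng, c1)          # IV
        return c1, c1, c3
    # ploidy rule
    if label == "II":
        return c1, _other_category(rng, c1), c1
    if label == "III":
        return c1, c1, _other_category(rng, c1)
    c2 = _other_category(rng, c1)              # IV
    return c1, c2, c2


def _plant_assay(cfg: SimConfig, rng: np.random.Generator, assay: str,
                 n_genotypes: int):
    """Modified mask, per-genotype categories, and series labels."""
    n = cfg.n_triads
    pi_mod = cfg.modified_props.get(assay, 0.8)
    n_mod = int(round(n * pi_mod))
    modified = np.zeros(n, dtype=bool)
    mod_idx = rng.permutation(n)[:n_mod]
    modified[mod_idx] = True

    cats = np.full((n, n_genotypes), UNMODIFIED, dtype=object)
    labels = np.full(n, "", dtype=object)

    props = cfg.category_props.get(assay, (0.85, 0.09, 0.06))
    c1_counts = largest_remainder(n_mod, props)
    c1_pool = np.repeat(np.array(CATEGORIES, dtype=object), c1_counts)
    c1 = c1_pool[rng.permutation(n_mod)]

    if cfg.series is not None:
        freqs = ((cfg.group_freqs or {}).get(assay)
                 or DEFAULT_GROUP_FREQS[cfg.series][assay])
        lab_counts = largest_remainder(n_mod, freqs)
        lab_pool = np.repeat(np.array(LABELS, dtype=object), lab_counts)
        lab = lab_pool[rng.permutation(n_mod)]
        for j, (idx, label) in enumerate(zip(mod_idx, lab)):
            cats[idx] = _series_triple(rng, label, c1[j], cfg.series)
            labels[idx] = label
    else:
        # independent planting: same category proportions per genotype
        cats[mod_idx, 0] = c1
        for g in range(1, n_genotypes):
            counts_g = largest_remainder(n_mod, props)
            pool = np.repeat(np.array(CATEGORIES, dtype=object), counts_g)
            cats[mod_idx, g] = pool[rng.permutation(n_mod)]
    return modified, cats, labels


def _replant_labels(cfg: SimConfig, rng: np.random.Generator,
                    cats: np.ndarray, labels: np.ndarray,
                    target_labels: np.ndarray, which: np.ndarray) -> None:
    """Overwrite series labels (expression-coupling): keep each triad's
    first-genotype category, re-derive the triple for the new label."""
    for idx in np.nonzero(which)[0]:
        c1 = cats[idx, 0]
        labels[idx] = target_labels[idx]
        cats[idx] = _series_triple(rng, labels[idx], c1, cfg.series)


# ---------------------------------------------------------------------------
# signal and counts
# ---------------------------------------------------------------------------

def _rel_for_category(cfg: SimConfig, rng: np.random.Generator,
                      cat: str) -> float:
    lo, hi = cfg.rel_balanced if cat == "A_eq_B" else cfg.rel_biased
    r = rng.uniform(lo, hi)
    return 1.0 - r if cat == "A_lt_B" else r


def _triad_signal(cfg: SimConfig, rng: np.random.Generator, assay: str,
                  compartment: np.ndarray) -> np.ndarray:
    """Total A+B TPM per triad: truncated-lognormal scale times the
    compartment weight (normalised to mean 1 over triads)."""
    n = cfg.n_triads
    z = np.maximum(rng.standard_normal(n), -2.5)
    s = 2.0 * cfg.mu * np.exp(cfg.sigma_log * z - cfg.sigma_log ** 2 / 2)
    weights = DEFAULT_ZONE_WEIGHTS.get(assay,
                                       DEFAULT_ZONE_WEIGHTS["RNA"])
    w = np.array([weights[c] for c in compartment])
    return s * (w / w.mean())


def _draw_counts(cfg: SimConfig, rng: np.random.Generator,
                 expectations: np.ndarray, phi: float) -> np.ndarray:
    if cfg.noiseless:
        return np.rint(expectations).astype(np.int64)
    if not np.isfinite(phi):
        return rng.poisson(expectations)
    p = phi / (phi + expectations)
    return rng.negative_binomial(phi, p)


def simulate_series(cfg: SimConfig) -> SimulatedDataset:
    """Generate a dataset for a three-genotype series (or, with
    ``cfg.series=None``, independently planted per-genotype categories).

    Identical configs (including seed) give byte-identical outputs.
    """
    if cfg.series is not None:
        if cfg.series not in DEFAULT_GROUP_FREQS:
            raise ValueError(f"unknown series {cfg.series!r}")
        if len(cfg.genotypes) != 3:
            raise ValueError("a series needs exactly three genotypes")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_triads
    triad_ids, triads, zones, compartment = _scaffold(cfg, rng)
    genotypes = list(cfg.genotypes)
    assays = list(cfg.assays)

    planted = {}
    for assay in assays:
        planted[assay] = _plant_assay(cfg, rng, assay, len(genotypes))

    # expression-label coupling: RNA transition labels partially copy the
    # H3K4me3 labels, so modification and expression tracking correlate
    if (cfg.series is not None and "RNA" in planted and
            "H3K4me3" in planted and cfg.expression_coupling > 0):
        mod_k4, _, lab_k4 = planted["H3K4me3"]
        mod_rna, cats_rna, lab_rna = planted["RNA"]
        both = mod_k4 & mod_rna
        couple = both & (rng.uniform(size=n) < cfg.expression_coupling)
        _replant_labels(cfg, rng, cats_rna, lab_rna, lab_k4, couple)

    # per-triad relative A share and total signal per genotype x assay
    rel = {}
    sig = {}
    for assay in assays:
        modified, cats, _ = planted[assay]
        s = _triad_signal(cfg, rng, assay, compartment)
        sig[assay] = s
        rel_a = np.full((n, len(genotypes)), np.nan)
        for g in range(len(genotypes)):
            for i in np.nonzero(modified)[0]:
                rel_a[i, g] = _rel_for_category(cfg, rng, cats[i, g])
        rel[assay] = rel_a

    counts = {}
    design_rows = []
    lengths = triads.gene_lengths()
    gene_order = pd.Index(np.concatenate(
        [triads.genes(sub).values for sub in SUBGENOMES]))
    len_kb = lengths.loc[gene_order].values / 1e3
    lib = cfg.library_size()

    for assay in assays:
        modified, cats, _ = planted[assay]
        phi = cfg.phi.get(assay, 10.0)
        for g, genotype in enumerate(genotypes):
            ploidy = PLOIDY.get(genotype, "AABB")
            # modified triads carry scale-free signal shapes; unmodified
            # homoeologs get a baseline drawn directly in TPM units.  The
            # shapes are then scaled so the column sums to one million,
            # which makes planted values realized TPMs (up to count noise).
            raw = np.zeros(3 * n)
            base = np.zeros(3 * n)
            if ploidy != "DD":
                raw[:n] = np.where(modified, rel[assay][:, g] * sig[assay],
                                   0.0)
                raw[n:2 * n] = np.where(
                    modified, (1 - rel[assay][:, g]) * sig[assay], 0.0)
                base[:n] = np.where(modified, 0.0,
                                    rng.uniform(0.01, cfg.epsilon, size=n))
                base[n:2 * n] = np.where(
                    modified, 0.0, rng.uniform(0.01, cfg.epsilon, size=n))
            if "DD" in ploidy:
                raw[2 * n:] = np.where(
                    modified, sig[assay] * rng.uniform(0.4, 0.6, size=n),
                    0.0)
                base[2 * n:] = np.where(
                    modified, 0.0, rng.uniform(0.01, cfg.epsilon, size=n))
            raw_mass = raw.sum()
            f = (1e6 - base.sum()) / raw_mass if raw_mass > 0 else 0.0
            e = raw * f + base
            # guarantee every modified triad clears the threshold with a
            # wide margin so planted categories stay recoverable
            tot_ab = e[:n] + e[n:2 * n]
            bump = modified & (tot_ab > 0) & (tot_ab < cfg.min_modified_tpm)
            if bump.any():
                factor = np.ones(n)
                factor[bump] = cfg.min_modified_tpm / tot_ab[bump]
                e[:n] *= factor
                e[n:2 * n] *= factor
            # expected counts proportional to abundance x length
            mass = e * len_kb
            m = lib * mass / mass.sum()
            for rep in range(1, cfg.replicates + 1):
                c = _draw_counts(cfg, rng, m, phi)
                counts[(genotype, assay, rep)] = pd.Series(
                    c, index=gene_order, name="count")
                design_rows.append({"sample_id":
                                    f"{genotype}_{assay}_rep{rep}",
                                    "genotype": genotype, "assay": assay,
                                    "replicate": rep})

    cat_rows = []
    lab_rows = []
    for assay in assays:
        modified, cats, labels = planted[assay]
        for g, genotype in enumerate(genotypes):
            cat_rows.append(pd.DataFrame({
                "triad_id": triad_ids, "genotype": genotype, "assay": assay,
                "category": cats[:, g]}))
        if cfg.series is not None:
            lab_rows.append(pd.DataFrame({
                "triad_id": triad_ids[modified], "assay": assay,
                "series": cfg.series, "label": labels[modified]}))
    truth_categories = pd.concat(cat_rows, ignore_index=True)
    truth_labels = (pd.concat(lab_rows, ignore_index=True) if lab_rows
                    else pd.DataFrame(columns=["triad_id", "assay",
                                               "series", "label"]))
    return SimulatedDataset(cfg, counts, triads, zones,
                            truth_categories, truth_labels,
                            pd.DataFrame(design_rows))


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Dataset with independently planted per-genotype categories."""
    if cfg.series is not None:
        raise ValueError("use simulate_series for series planting")
    return simulate_series(cfg)


def domestication_config(**overrides) -> SimConfig:
    """Study conditions for the WTW -> DTW -> ETW tracking analysis."""
    base = dict(series="domestication",
                genotypes=("WTW", "DTW", "ETW"),
                assays=("H3K4me3", "H3K27me3", "RNA"))
    base.update(overrides)
    return SimConfig(**base)


def ploidy_config(**overrides) -> SimConfig:
    """Study conditions for the TAA10 -> ETW -> XX329 tracking analysis."""
    base = dict(series="ploidy",
                genotypes=("TAA10", "ETW", "XX329"),
                assays=("H3K4me3", "H3K27me3", "RNA"))
    base.update(overrides)
    return SimConfig(**base)
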
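"""Seedable synthetic study generator with planted ground truth.

Emulates the five tabular inputs of the pipeline — a Q-TOF peak table,
compound->target predictions, per-source disease-target tables, a STRING-like
PPI edge list and a GO/KEGG-style annotation file — so every stage can be
exercised and verified without any database download.  Planted structure
(main-ingredient compounds with boosted connectivity, high-degree PPI hubs,
enriched annotation terms, a fixed compound/disease intersection) is recorded
in a ``truth`` object that is consistent with the emitted tables by
construction.

Counts are planted exactly, not in expectation: the default configuration
reproduces the published study scale (41 compounds of which 32 connect to
the 262-gene therapeutic intersection through 685 links; disease sources
screening to 2670/542/634/3 genes and merging to 3225; a PPI network of 222
connected genes and 1205 super-threshold edges with 10 planted hubs; 20
planted pathways covering 132 network targets reached by 29 compounds), so
summary statistics of a generated study are identical for every seed while
all memberships, scores and orderings are seed-dependent.

Disease scores are drawn in two separated strata (screened genes in
[10, 40], filler genes in [0.2, 1.0]); with the default 4 filler rows per
screened gene the per-source mean provably falls strictly between the
strata, so the score >= mean screen keeps exactly the planted high-score
genes for any seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .enrichment import AnnotationDB, Term, write_gmt
from .mass_annotation import (
    ADDUCTS,
    adduct_mz,
    load_reference_peaks,
    monoisotopic_mass,
    parse_formula,
)

HUB_SYMBOLS = (
    "PIK3R1", "PIK3CA", "SRC", "MAPK1", "AKT1",
    "HSP90AA1", "HRAS", "STAT3", "FYN", "RHOA",
)

__all__ = [
    "SourceSpec",
    "PPISpec",
    "AnnotationSpec",
    "PeakSpec",
    "StudyConfig",
    "SyntheticStudy",
    "generate_study",
    "generate_peaks",
]


class InfeasibleConfig(ValueError):
    """A study configuration whose planted counts cannot coexist."""


@dataclass(frozen=True)
class SourceSpec:
    """One disease-target source: name, score family, planted screened size."""

    name: str
    family: str  # "lognormal" | "uniform" | "constant"
    n_screened: int


@dataclass(frozen=True)
class PPISpec:
    n_connected: int = 222          # genes left after free-gene removal
    n_edges: int = 1205             # super-threshold edges
    n_subthreshold_edges: int = 600
    n_planted_hubs: int = 10
    hub_degree_range: tuple[int, int] = (37, 56)
    nonhub_degree_cap: int = 30
    score_threshold: float = 0.9


@dataclass(frozen=True)
class AnnotationSpec:
    n_terms: tuple[int, int, int, int] = (40, 15, 20, 40)      # BP, CC, MF, KEGG
    n_planted: tuple[int, int, int, int] = (5, 3, 4, 20)
    term_size_range: tuple[int, int] = (12, 60)
    planted_overlap_fraction: float = 0.5


@dataclass(frozen=True)
class PeakSpec:
    n_peaks: int = 41
    noise_ppm: float = 4.5          # |uniform| perturbation for in-tolerance peaks
    fraction_outside: float = 0.1   # peaks perturbed beyond the 5 ppm window
    outside_ppm_range: tuple[float, float] = (7.5, 15.0)
    # formate adducts are omitted: [M+COOH]- of M is exactly isobaric with
    # [M-H]- of M+CH2O2, which makes "recover the generating formula"
    # ill-posed for such peaks
    adducts: tuple[str, ...] = ("[M+H]+", "[M+Na]+", "[M-H]-", "[M+Cl]-")


@dataclass(frozen=True)
class StudyConfig:
    """Planted study conditions; the seed fully determines the output."""

    seed: int = 0
    n_compounds: int = 41
    n_connected_compounds: int = 32
    n_planted_ingredients: int = 7
    planted_degree_boost: float = 5.0
    targets_per_compound: tuple[int, int] = (8, 15)   # baseline network degree
    n_ct_edges: int = 685
    intersection_size: int = 262
    n_compound_only_genes: int = 209   # compound union = intersection + these
    n_prediction_rows: int = 1157      # kept (probability > 0) prediction rows
    n_zero_probability_rows: int = 70
    disease_union_size: int = 3225
    sources: tuple[SourceSpec, ...] = (
        SourceSpec("GeneCards", "lognormal", 2670),
        SourceSpec("OMIM", "lognormal", 542),
        SourceSpec("DisGeNET", "uniform", 634),
        SourceSpec("TTD", "constant", 3),
    )
    filler_rows_per_screened: float = 4.0
    n_ctp_targets: int = 132           # network targets covered by planted pathways
    n_ctp_excluded_compounds: int = 3  # connected compounds outside every pathway
    ppi: PPISpec = field(default_factory=PPISpec)
    annotation: AnnotationSpec = field(default_factory=AnnotationSpec)
    peaks: PeakSpec = field(default_factory=PeakSpec)

    @classmethod
    def default(cls, seed: int = 0) -> "StudyConfig":
        return cls(seed=seed)

    @classmethod
    def small(cls, seed: int = 0) -> "StudyConfig":
        """Scaled-down conditions for fast repeated-seed testing."""
        return cls(
            seed=seed,
            n_compounds=12,
            n_connected_compounds=9,
            n_planted_ingredients=3,
            targets_per_compound=(3, 5),
            n_ct_edges=84,
            intersection_size=30,
            n_compound_only_genes=15,
            n_prediction_rows=110,
            n_zero_probability_rows=6,
            disease_union_size=90,
            sources=(
                SourceSpec("GeneCards", "lognormal", 50),
                SourceSpec("OMIM", "lognormal", 20),
                SourceSpec("DisGeNET", "uniform", 25),
                SourceSpec("TTD", "constant", 3),
            ),
            n_ctp_targets=18,
            n_ctp_excluded_compounds=1,
            ppi=PPISpec(
                n_connected=24,
                n_edges=60,
                n_subthreshold_edges=30,
                n_planted_hubs=3,
                hub_degree_range=(10, 13),
                nonhub_degree_cap=7,
            ),
            annotation=AnnotationSpec(
                n_terms=(10, 6, 8, 10),
                n_planted=(2, 1, 2, 5),
                term_size_range=(8, 20),
            ),
            peaks=PeakSpec(n_peaks=12),
        )

    # -- feasibility -------------------------------------------------------

    def validate(self) -> None:
        def need(cond: bool, constraint: str) -> None:
            if not cond:
                raise InfeasibleConfig(constraint)

        lo, hi = self.targets_per_compound
        n_base = self.n_connected_compounds - self.n_planted_ingredients
        need(self.n_planted_ingredients >= 0, "n_planted_ingredients >= 0")
        need(n_base >= 0, "n_planted_ingredients <= n_connected_compounds")
        need(self.n_connected_compounds <= self.n_compounds,
             "n_connected_compounds <= n_compounds")
        need(0 < lo <= hi, "targets_per_compound must be a positive range")
        mean_deg = self.n_ct_edges / max(self.n_connected_compounds, 1)
        need(hi < mean_deg,
             "baseline targets_per_compound max must stay below the mean degree "
             f"{mean_deg:.2f} (planted compounds must be separable)")
        planted_total = self.n_ct_edges - n_base * (lo + hi) // 2
        need(self.n_ct_edges > n_base * hi,
             "n_ct_edges too small for baseline compounds")
        if self.n_planted_ingredients:
            need(planted_total <= self.n_planted_ingredients * self.intersection_size,
                 "planted compound degrees exceed intersection_size")
        need(self.intersection_size <= self.disease_union_size,
             "intersection_size <= disease_union_size")
        need(self.n_ctp_targets <= self.intersection_size,
             "n_ctp_targets <= intersection_size")
        need(self.n_ctp_excluded_compounds <= n_base,
             "n_ctp_excluded_compounds must be baseline (non-planted) compounds")
        need(self.n_ctp_excluded_compounds * hi
             <= self.intersection_size - self.n_ctp_targets,
             "excluded compounds need enough non-pathway targets")
        need(self.n_prediction_rows >= self.n_ct_edges + self.n_compound_only_genes,
             "n_prediction_rows must cover network edges plus compound-only genes")
        extra = self.n_prediction_rows - self.n_ct_edges
        need(extra <= self.n_compounds * self.n_compound_only_genes,
             "n_prediction_rows exceeds distinct compound/gene pairs")
        sizes = [s.n_screened for s in self.sources]
        need(all(v >= 1 for v in sizes), "each source screens to >= 1 gene")
        need(max(sizes, default=0) <= self.disease_union_size,
             "source screened size <= disease_union_size")
        leftover = self.disease_union_size - max(sizes, default=0)
        need(sum(sorted(sizes)[:-1]) >= leftover,
             "remaining sources cannot cover the disease union")
        r = self.filler_rows_per_screened
        need(30 / 9 < r < 45 / 4,
             "filler_rows_per_screened must keep the per-source mean strictly "
             "between the score strata (feasible range ~3.34-11.25)")
        p = self.ppi
        need(p.n_connected <= self.intersection_size,
             "ppi.n_connected <= intersection_size")
        need(p.n_planted_hubs <= min(p.n_connected, len(HUB_SYMBOLS)),
             "ppi.n_planted_hubs <= ppi.n_connected (and <= reserved hub symbols)")
        need(p.hub_degree_range[0] > p.nonhub_degree_cap,
             "hub degrees must exceed nonhub_degree_cap for recoverable hubs")
        need(p.hub_degree_range[1] <= p.n_connected - p.n_planted_hubs,
             "hub degree exceeds available non-hub partners")
        n_nonhub = p.n_connected - p.n_planted_hubs
        need(2 * p.n_edges <= n_nonhub * p.nonhub_degree_cap
             + p.n_planted_hubs * p.hub_degree_range[1] + n_nonhub,
             "ppi.n_edges exceeds degree-cap capacity")
        a = self.annotation
        need(len(a.n_terms) == 4 and len(a.n_planted) == 4,
             "annotation term counts must cover BP, CC, MF, KEGG")
        need(all(k <= n for k, n in zip(a.n_planted, a.n_terms)),
             "annotation.n_planted <= annotation.n_terms per category")
        need(0 < a.planted_overlap_fraction <= 1,
             "planted_overlap_fraction in (0, 1]")
        need(0 <= self.peaks.fraction_outside <= 1,
             "peaks.fraction_outside in [0, 1]")


@dataclass
class SyntheticStudy:
    """Generated input bundle plus its planted ground truth."""

    config: StudyConfig
    peaks: pd.DataFrame
    predictions: pd.DataFrame
    disease: pd.DataFrame
    ppi: pd.DataFrame
    annotations: AnnotationDB
    truth: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.peaks.to_csv(out / "peaks.tsv", sep="\t", index=False)
        self.predictions.to_csv(out / "predictions.tsv", sep="\t", index=False)
        self.disease.to_csv(out / "disease.tsv", sep="\t", index=False)
        self.ppi.to_csv(out / "ppi.tsv", sep="\t", index=False)
        write_gmt(self.annotations, out / "annotations.gmt")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# RNG sub-streams: one stream per table, keyed by a fixed index, so adding a
# table never perturbs the draws of an existing one.

_STREAMS = {
    "layout": 0,
    "peaks": 1,
    "predictions": 2,
    "disease": 3,
    "ppi": 4,
    "annotation": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


def _choice(rng: np.random.Generator, items: list[str], size: int,
            replace: bool = False) -> list[str]:
    idx = rng.choice(len(items), size=size, replace=replace)
    return [items[i] for i in idx]


# ---------------------------------------------------------------------------
# Degree allocation helpers


def _split_total(total: int, n: int, lo: int, hi: int,
                 rng: np.random.Generator) -> list[int]:
    """n integers in [lo, hi] summing exactly to total, jittered randomly."""
    if n == 0:
        if total:
            raise InfeasibleConfig("cannot place edges on zero compounds")
        return []
    if not (n * lo <= total <= n * hi):
        raise InfeasibleConfig(
            f"cannot split {total} into {n} parts within [{lo}, {hi}]")
    vals = [total // n] * n
    for i in range(total - sum(vals)):
        vals[i] += 1
    for _ in range(6 * n):
        i, j = int(rng.integers(n)), int(rng.integers(n))
        if i == j:
            continue
        d = int(rng.integers(1, 3))
        if vals[i] - d >= lo and vals[j] + d <= hi:
            vals[i] -= d
            vals[j] += d
    rng.shuffle(vals)
    return [int(v) for v in vals]


# ---------------------------------------------------------------------------
# Score strata: screened genes in [10, 40], fillers in [0.2, 1.0]; the family
# only shapes the distribution inside its stratum.

_HIGH_LO, _HIGH_HI = 10.0, 40.0
_LOW_LO, _LOW_HI = 0.2, 1.0


def _stratum_scores(rng: np.random.Generator, n: int, family: str,
                    lo: float, hi: float) -> np.ndarray:
    if family == "lognormal":
        raw = rng.lognormal(mean=0.0, sigma=0.6, size=n)
    elif family == "uniform":
        raw = rng.uniform(size=n)
    else:
        raise ValueError(f"unknown score family {family!r}")
    if n == 1:
        return np.array([(lo + hi) / 2])
    span = raw.max() - raw.min()
    scaled = (raw - raw.min()) / span if span else np.zeros(n)
    return lo + scaled * (hi - lo) * 0.999 + (hi - lo) * 5e-4


# ---------------------------------------------------------------------------
# Generators


def generate_peaks(config: StudyConfig, rng: np.random.Generator | None = None
                   ) -> tuple[pd.DataFrame, dict]:
    """Peak table drawn from the bundled compound formula pool.

    Observed m/z is the theoretical adduct m/z perturbed by a uniform error
    within ``noise_ppm``; a configurable fraction is pushed beyond the 5 ppm
    fitting window to act as planted negatives.
    """
    spec = config.peaks
    rng = _rng(config.seed, "peaks") if rng is None else rng
    pool = load_reference_peaks()
    pool = pool.loc[pool["consistent"] == 1, "known_formula"].tolist()
    adduct_names = list(spec.adducts)
    rows = []
    outside_ids = []
    n_outside = int(round(spec.n_peaks * spec.fraction_outside))
    outside_flags = np.array([True] * n_outside
                             + [False] * (spec.n_peaks - n_outside))
    rng.shuffle(outside_flags)
    for i in range(spec.n_peaks):
        formula = pool[int(rng.integers(len(pool)))]
        adduct = ADDUCTS[adduct_names[int(rng.integers(len(adduct_names)))]]
        theo = adduct_mz(monoisotopic_mass(parse_formula(formula)), adduct)
        if outside_flags[i]:
            lo, hi = spec.outside_ppm_range
            ppm = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
            outside_ids.append(f"P{i + 1:03d}")
        else:
            ppm = float(rng.uniform(-spec.noise_ppm, spec.noise_ppm))
        rows.append({
            "peak_id": f"P{i + 1:03d}",
            "rt_min": round(float(rng.uniform(0.5, 45.0)), 2),
            "observed_mz": round(theo * (1 + ppm * 1e-6), 5),
            "polarity": adduct.polarity,
            "known_formula": formula,
        })
    table = pd.DataFrame(rows).sort_values("rt_min", kind="stable",
                                           ignore_index=True)
    truth = {"peaks_outside_tolerance": sorted(outside_ids)}
    return table, truth


def _gene_layout(config: StudyConfig, rng: np.random.Generator) -> dict:
    """Name the gene strata: intersection, compound-only, disease-only."""
    n_hub = config.ppi.n_planted_hubs
    hubs = list(HUB_SYMBOLS[:n_hub])
    intersection = hubs + [f"TG{i:04d}" for i in range(config.intersection_size - n_hub)]
    compound_only = [f"CP{i:04d}" for i in range(config.n_compound_only_genes)]
    disease_only = [f"DS{i:04d}" for i in
                    range(config.disease_union_size - config.intersection_size)]
    for pool in (intersection, compound_only, disease_only):
        rng.shuffle(pool)
    return {
        "hubs": hubs,
        "intersection": intersection,
        "compound_only": compound_only,
        "disease_only": disease_only,
    }


def _compound_layout(config: StudyConfig, layout: dict,
                     rng: np.random.Generator) -> dict:
    """Pick compounds, degrees and per-compound target sets."""
    compounds = [f"CMP{i + 1:02d}" for i in range(config.n_compounds)]
    rng.shuffle(compounds)
    connected = sorted(compounds[: config.n_connected_compounds])
    disconnected = sorted(compounds[config.n_connected_compounds:])
    planted = sorted(_choice(rng, connected, config.n_planted_ingredients))
    baseline = [c for c in connected if c not in planted]

    lo, hi = config.targets_per_compound
    degrees = {c: int(rng.integers(lo, hi + 1)) for c in baseline}
    planted_total = config.n_ct_edges - sum(degrees.values())
    mean_deg = config.n_ct_edges / config.n_connected_compounds
    if planted:
        # strictly above the overall mean (the screen requires it), centred
        # near boost x baseline with modest jitter so no planted compound
        # lags far behind its peers
        share = planted_total / len(planted)
        p_lo = max(int(mean_deg) + 1, int(share * 0.8))
        p_hi = min(config.intersection_size,
                   max(p_lo, int(np.ceil(share * 1.2))))
        for c, d in zip(planted, _split_total(planted_total, len(planted),
                                              p_lo, p_hi, rng)):
            degrees[c] = d
    elif planted_total:
        raise InfeasibleConfig("edge total unreachable without planted compounds")

    intersection = layout["intersection"]
    excluded = sorted(_choice(rng, baseline, config.n_ctp_excluded_compounds))
    included = [c for c in connected if c not in excluded]
    shuffled = list(intersection)
    rng.shuffle(shuffled)
    ctp_targets = sorted(shuffled[: config.n_ctp_targets])
    non_ctp = shuffled[config.n_ctp_targets:]

    targets: dict[str, set[str]] = {c: set() for c in connected}
    # excluded compounds draw only from non-pathway targets
    for c in excluded:
        targets[c] = set(_choice(rng, non_ctp, degrees[c]))
    capacity = {c: degrees[c] - len(targets[c]) for c in connected}
    # every included compound is guaranteed one pathway target
    ctp_pool = list(ctp_targets)
    rng.shuffle(ctp_pool)
    for c in included:
        targets[c].add(ctp_pool.pop())
        capacity[c] -= 1
    # deal every still-uncovered intersection gene to a compound with room
    covered = set().union(*targets.values())
    uncovered = [g for g in intersection if g not in covered]
    rng.shuffle(uncovered)
    for g in uncovered:
        eligible = [c for c in included if capacity[c] > 0] if g in set(ctp_targets) \
            else [c for c in connected if capacity[c] > 0 and
                  (c not in excluded or g not in set(ctp_targets))]
        eligible = [c for c in eligible if g not in targets[c]]
        if not eligible:
            raise InfeasibleConfig("ran out of compound capacity while covering targets")
        c = eligible[int(rng.integers(len(eligible)))]
        targets[c].add(g)
        capacity[c] -= 1
    # fill the remaining capacity with arbitrary eligible targets
    ctp_set = set(ctp_targets)
    for c in connected:
        pool = non_ctp if c in excluded else intersection
        avail = [g for g in pool if g not in targets[c]]
        rng.shuffle(avail)
        take = capacity[c]
        targets[c].update(avail[:take])
        if len(targets[c]) != degrees[c]:
            raise InfeasibleConfig("target pool exhausted for a compound")
    assert sum(len(v) for v in targets.values()) == config.n_ct_edges
    assert set().union(*targets.values()) == set(intersection)
    ctp_compounds = sorted(c for c in connected if targets[c] & ctp_set)
    assert ctp_compounds == sorted(included)
    return {
        "connected": connected,
        "disconnected": disconnected,
        "planted": planted,
        "targets": targets,
        "ctp_targets": ctp_targets,
        "ctp_compounds": sorted(included),
        "all_compounds": sorted(compounds),
    }


def _prediction_table(config: StudyConfig, layout: dict, cl: dict,
                      rng: np.random.Generator) -> pd.DataFrame:
    rows: list[tuple[str, str, float]] = []
    for c in cl["connected"]:
        for g in sorted(cl["targets"][c]):
            rows.append((c, g, float(rng.uniform(0.05, 1.0))))
    # compound-only genes: every gene appears, every disconnected compound too
    co = list(layout["compound_only"])
    rng.shuffle(co)
    all_compounds = cl["all_compounds"]
    pairs: set[tuple[str, str]] = set()
    carriers = list(cl["disconnected"])
    for i, g in enumerate(co):
        c = carriers[i] if i < len(carriers) else \
            all_compounds[int(rng.integers(len(all_compounds)))]
        pairs.add((c, g))
    n_extra = config.n_prediction_rows - config.n_ct_edges - len(pairs)
    guard = 0
    while n_extra > 0 and guard < 100_000:
        c = all_compounds[int(rng.integers(len(all_compounds)))]
        g = co[int(rng.integers(len(co)))]
        if (c, g) not in pairs:
            pairs.add((c, g))
            n_extra -= 1
        guard += 1
    if n_extra > 0:
        raise InfeasibleConfig("could not place the requested prediction rows")
    for c, g in sorted(pairs):
        rows.append((c, g, float(rng.uniform(0.05, 1.0))))
    # planted negatives: zero-probability rows that every screen must drop
    existing = {(c, g) for c, g, _ in rows}
    zero_pool = layout["compound_only"] + layout["intersection"]
    placed = 0
    guard = 0
    while placed < config.n_zero_probability_rows and guard < 100_000:
        c = all_compounds[int(rng.integers(len(all_compounds)))]
        g = zero_pool[int(rng.integers(len(zero_pool)))]
        if (c, g) not in existing:
            existing.add((c, g))
            rows.append((c, g, 0.0))
            placed += 1
        guard += 1
    df = pd.DataFrame(rows, columns=["compound_id", "gene", "probability"])
    shuffled = df.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    return shuffled.reset_index(drop=True)


def _disease_table(config: StudyConfig, layout: dict,
                   rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    union = layout["intersection"] + layout["disease_only"]
    order = list(union)
    rng.shuffle(order)
    sizes = [s.n_screened for s in config.sources]
    largest = int(np.argmax(sizes))
    screened: dict[str, list[str]] = {}
    screened[config.sources[largest].name] = order[: sizes[largest]]
    leftover = order[sizes[largest]:]
    # distribute the leftover across the remaining sources, then pad randomly
    rest = [i for i in range(len(config.sources)) if i != largest]
    pos = 0
    for i in rest:
        src = config.sources[i]
        take = min(len(leftover) - pos, sizes[i])
        chunk = leftover[pos: pos + take]
        pos += take
        if len(chunk) < sizes[i]:
            pad_pool = [g for g in order if g not in set(chunk)]
            chunk = chunk + _choice(rng, pad_pool, sizes[i] - len(chunk))
        screened[src.name] = chunk
    if pos < len(leftover):
        raise InfeasibleConfig("remaining sources cannot cover the disease union")

    frames = []
    filler_counter = 0
    for src in config.sources:
        genes = screened[src.name]
        if src.family == "constant":
            frames.append(pd.DataFrame({
                "source": src.name, "gene": genes, "score": [""] * len(genes)}))
            continue
        n_fill = int(round(config.filler_rows_per_screened * len(genes)))
        fillers = [f"LW{filler_counter + i:05d}" for i in range(n_fill)]
        filler_counter += n_fill
        high = _stratum_scores(rng, len(genes), src.family, _HIGH_LO, _HIGH_HI)
        low = _stratum_scores(rng, n_fill, src.family, _LOW_LO, _LOW_HI)
        frame = pd.DataFrame({
            "source": src.name,
            "gene": genes + fillers,
            "score": np.round(np.concatenate([high, low]), 4),
        })
        frames.append(frame.sample(frac=1.0,
                                   random_state=int(rng.integers(2**31))))
    df = pd.concat(frames, ignore_index=True)
    truth = {"screened_per_source": {s.name: len(screened[s.name])
                                     for s in config.sources}}
    return df, truth


def _ppi_table(config: StudyConfig, layout: dict,
               rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    spec = config.ppi
    hubs = layout["hubs"]
    others = [g for g in layout["intersection"] if g not in hubs]
    rng.shuffle(others)
    nonhubs = sorted(others[: spec.n_connected - len(hubs)])
    free = sorted(others[spec.n_connected - len(hubs):])
    degree = {g: 0 for g in hubs + nonhubs}
    edges: set[tuple[str, str]] = set()

    def add(a: str, b: str) -> bool:
        e = (a, b) if a < b else (b, a)
        if a == b or e in edges:
            return False
        edges.add(e)
        degree[a] += 1
        degree[b] += 1
        return True

    # 1. coverage: every non-hub gets one edge up front
    pair_order = list(nonhubs)
    rng.shuffle(pair_order)
    for i in range(0, len(pair_order) - 1, 2):
        add(pair_order[i], pair_order[i + 1])
    if len(pair_order) % 2:
        partner = pair_order[int(rng.integers(len(pair_order) - 1))]
        add(pair_order[-1], partner)
    # 2. hubs reach their planted degrees through non-hub partners
    d_lo, d_hi = spec.hub_degree_range
    hub_deg = sorted((int(rng.integers(d_lo, d_hi + 1)) for _ in hubs),
                     reverse=True)
    for h, target_deg in zip(hubs, hub_deg):
        partners = [g for g in nonhubs if degree[g] < spec.nonhub_degree_cap]
        rng.shuffle(partners)
        placed = 0
        for g in partners:
            if placed == target_deg:
                break
            if add(h, g):
                placed += 1
        if placed < target_deg:
            raise InfeasibleConfig("not enough non-hub partners for planted hubs")
    # 3. fill with non-hub pairs up to the exact edge count
    all_pairs = [(a, b) for i, a in enumerate(nonhubs) for b in nonhubs[i + 1:]]
    rng.shuffle(all_pairs)
    for a, b in all_pairs:
        if len(edges) >= spec.n_edges:
            break
        if degree[a] >= spec.nonhub_degree_cap or degree[b] >= spec.nonhub_degree_cap:
            continue
        add(a, b)
    if len(edges) != spec.n_edges:
        raise InfeasibleConfig("ppi.n_edges unreachable under the degree cap")

    rows = [{"gene_a": a, "gene_b": b,
             "combined_score": round(float(rng.uniform(spec.score_threshold, 1.0)), 3)}
            for a, b in sorted(edges)]
    # sub-threshold noise, may also touch the planted free genes
    noise_pool = layout["intersection"]
    placed = 0
    guard = 0
    seen_noise: set[tuple[str, str]] = set(edges)
    while placed < spec.n_subthreshold_edges and guard < 200_000:
        a = noise_pool[int(rng.integers(len(noise_pool)))]
        b = noise_pool[int(rng.integers(len(noise_pool)))]
        e = (a, b) if a < b else (b, a)
        if a != b and e not in seen_noise:
            seen_noise.add(e)
            rows.append({"gene_a": e[0], "gene_b": e[1],
                         "combined_score": round(float(
                             rng.uniform(0.3, spec.score_threshold - 0.002)), 3)})
            placed += 1
        guard += 1
    df = pd.DataFrame(rows).sample(frac=1.0, random_state=int(rng.integers(2**31)))
    truth = {"planted_hubs": sorted(hubs),
             "ppi_connected_genes": len(hubs) + len(nonhubs),
             "ppi_free_genes": sorted(free)}
    return df.reset_index(drop=True), truth


def _annotation_db(config: StudyConfig, layout: dict, cl: dict,
                   rng: np.random.Generator) -> tuple[AnnotationDB, dict]:
    spec = config.annotation
    query = set(layout["intersection"])
    background_genes = (layout["intersection"] + layout["compound_only"]
                        + layout["disease_only"])
    background = sorted(background_genes)
    non_query = sorted(set(background) - query)
    N, n = len(background), len(query)
    frac = spec.planted_overlap_fraction
    size_lo, size_hi = spec.term_size_range
    terms: list[Term] = []
    planted_ids: list[str] = []
    categories = ("BP", "CC", "MF", "KEGG")

    def planted_term(term_id: str, name: str, cat: str,
                     overlap_pool: list[str], forced: list[str]) -> Term:
        """A term guaranteed to pass the p < 0.01 screen (p <= 1e-3)."""
        members = set(forced)
        k = len(members & query)
        pool = [g for g in overlap_pool if g not in members]
        rng.shuffle(pool)
        while True:
            n_fill = max(0, int(round(len(members & query) * (1 - frac) / frac)))
            K = len(members & query) + n_fill
            p = float(hypergeom.sf(len(members & query) - 1, N, K, n))
            if p <= 1e-3 and len(members & query) >= 3:
                break
            if not pool:
                raise InfeasibleConfig(
                    f"cannot make planted term {term_id} significant")
            members.add(pool.pop())
        k = len(members & query)
        n_fill = max(0, int(round(k * (1 - frac) / frac)))
        fill_pool = [g for g in non_query if g not in members]
        members |= set(_choice(rng, fill_pool, n_fill))
        return Term(term_id, name, cat, frozenset(members))

    # KEGG planted terms jointly cover the CTP target set, and only it,
    # inside the query; decoy KEGG terms never touch the query.
    ctp_targets = list(cl["ctp_targets"])
    n_kegg_planted = spec.n_planted[3]
    deal = [[] for _ in range(n_kegg_planted)]
    order = list(ctp_targets)
    rng.shuffle(order)
    for i, g in enumerate(order):
        deal[i % n_kegg_planted].append(g)
    for j in range(n_kegg_planted):
        term_id = f"hsa{j + 1:04d}"
        t = planted_term(term_id, f"Pathway {j + 1}", "KEGG",
                         [g for g in ctp_targets if g not in deal[j]], deal[j])
        terms.append(t)
        planted_ids.append(term_id)
    n_kegg_decoys = spec.n_terms[3] - n_kegg_planted
    for j in range(n_kegg_decoys):
        size = int(rng.integers(size_lo, size_hi + 1))
        genes = _choice(rng, non_query, min(size, len(non_query)))
        terms.append(Term(f"hsa9{j + 1:03d}", f"Decoy pathway {j + 1}", "KEGG",
                          frozenset(genes)))
    # GO categories: planted terms overlap the query, the rest are random
    query_list = sorted(query)
    for ci, cat in enumerate(categories[:3]):
        n_planted = spec.n_planted[ci]
        for j in range(n_planted):
            term_id = f"GO:{ci + 1}{j:06d}"
            seed_genes = _choice(rng, query_list, 3)
            t = planted_term(term_id, f"{cat} planted process {j + 1}", cat,
                             [g for g in query_list if g not in seed_genes],
                             seed_genes)
            terms.append(t)
            planted_ids.append(term_id)
        for j in range(spec.n_terms[ci] - n_planted):
            size = int(rng.integers(size_lo, size_hi + 1))
            genes = _choice(rng, background, min(size, len(background)))
            terms.append(Term(f"GO:{ci + 1}9{j:05d}", f"{cat} random process {j + 1}",
                              cat, frozenset(genes)))
    from .target_assembly import GeneSet
    db = AnnotationDB(terms, background=GeneSet("background", frozenset(background)))
    truth = {"planted_terms": sorted(planted_ids)}
    return db, truth


def generate_study(config: StudyConfig | None = None) -> SyntheticStudy:
    """Generate the full input bundle; deterministic given ``config.seed``."""
    config = StudyConfig() if config is None else config
    config.validate()
    layout_rng = _rng(config.seed, "layout")
    layout = _gene_layout(config, layout_rng)
    cl = _compound_layout(config, layout, layout_rng)

    peaks, peaks_truth = generate_peaks(config)
    predictions = _prediction_table(config, layout, cl,
                                    _rng(config.seed, "predictions"))
    disease, disease_truth = _disease_table(config, layout,
                                            _rng(config.seed, "disease"))
    ppi, ppi_truth = _ppi_table(config, layout, _rng(config.seed, "ppi"))
    annotations, ann_truth = _annotation_db(config, layout, cl,
                                            _rng(config.seed, "annotation"))

    truth = {
        "planted_ingredients": cl["planted"],
        "planted_intersection": sorted(layout["intersection"]),
        "connected_compounds": cl["connected"],
        "ctp_compounds": cl["ctp_compounds"],
        "ctp_targets": cl["ctp_targets"],
        "compound_union_size": config.intersection_size + config.n_compound_only_genes,
        "disease_union_size": config.disease_union_size,
        **peaks_truth,
        **disease_truth,
        **ppi_truth,
        **ann_truth,
    }
    return SyntheticStudy(config, peaks, predictions, disease, ppi,
                          annotations, truth)
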
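"""Synthetic-cohort generator.

Produces tumor RNA-seq callsets with matched DNA truth, annotation
resources, per-sample depth tracks, expression, clinical covariates, and
proportional-hazards survival outcomes.  The generative mechanisms mirror
the biology the pipeline must cope with: coverage proportional to
expression, distinct VAF/recurrence signatures for somatic vs germline vs
RNA-editing vs artifact calls, loss of truncating tumor-suppressor variants
from RNA (nonsense-mediated decay), and a lenient caller floor.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import annotate as ann_mod
from .annotate import GENETIC_CODE, TranscriptModel, attach_reference, classify_effect
from .io_core import (
    ClinicalRecord,
    DepthTrack,
    FunctionalClass,
    GeneSet,
    VariantRecord,
    write_bed,
    write_clinical,
    write_gene_sets,
    write_vcf,
)

__all__ = ["GeneSpec", "SimulationParams", "SimulationBundle", "simulate_cohort",
           "simulate_survival", "write_bundle", "default_gene_panel", "bundle_index"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneSpec:
    gene: str
    role: str  # oncogene | tumor_suppressor | neutral
    expression: float  # FPKM-like mean coverage scale

    def __post_init__(self):
        if self.role not in {"oncogene", "tumor_suppressor", "neutral"}:
            raise ValueError(f"bad gene role {self.role}")


def default_gene_panel(n_genes: int = 12, rng: Optional[np.random.Generator] = None):
    rng = rng or np.random.default_rng(0)
    roles = ["oncogene", "tumor_suppressor", "neutral"]
    panel = []
    for i in range(n_genes):
        expr = float(np.round(rng.lognormal(mean=3.4, sigma=0.5), 2))
        panel.append(GeneSpec(gene=f"GENE{i + 1:02d}", role=roles[i % 3], expression=expr))
    return panel


@dataclass
class SimulationParams:
    seed: int
    n_samples: int = 50
    gene_panel: Optional[Sequence[GeneSpec]] = None
    somatic_rate: float = 6.0
    germline_rate: float = 4.0
    editing_rate: float = 2.0
    artifact_rate: float = 3.0
    somatic_vaf_alpha: float = 3.0
    somatic_vaf_beta: float = 7.0
    artifact_vaf_max: float = 0.05
    size_factor: float = 1.0
    dna_depth: float = 80.0
    nmd_dropout: float = 0.7
    caller_min_vaf: float = 0.02
    caller_min_alt_depth: int = 2
    hotspot_fraction: float = 0.35
    n_hotspots: int = 8
    cosmic_hotspot_fraction: float = 1.0
    clinical_db_fraction: float = 0.25
    editing_db_coverage: float = 1.0
    n_snp_pool: int = 60
    n_editing_pool: int = 40
    n_recurrent_artifacts: int = 6
    recurrent_artifact_fraction: float = 0.2
    low_depth_artifact_fraction: float = 0.35
    n_normals: int = 10
    baseline_hazard: float = 0.004  # per month
    gene_log_hrs: dict = field(default_factory=dict)  # gene -> log HR when mutated
    censoring_fraction: float = 0.3
    max_followup_months: float = 120.0

    def __post_init__(self):
        for name in ("somatic_rate", "germline_rate", "editing_rate", "artifact_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("nmd_dropout", "hotspot_fraction", "censoring_fraction",
                     "editing_db_coverage", "cosmic_hotspot_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.gene_panel is None:
            self.gene_panel = default_gene_panel(rng=np.random.default_rng(self.seed ^ 0xA5))
        if not any(g.expression > 0 for g in self.gene_panel):
            raise ValueError("at least one gene must be expressed")


@dataclass
class SimulationBundle:
    params: SimulationParams
    reference: dict                 # chrom -> sequence
    transcript_models: list
    rna_calls: list                 # VariantRecord (all samples)
    dna_somatic: list
    dna_germline: list
    normal_callsets: list           # list of lists, for panel-of-normals
    truth: pd.DataFrame             # sample_id, chrom, pos, ref, alt, label
    depth_tracks: dict              # sample_id -> DepthTrack
    expression: pd.DataFrame        # gene x sample FPKM-like
    clinical: list                  # ClinicalRecord
    resources: dict                 # name -> DataFrame / list (annotation TSV payloads)
    gene_sets: list
    sample_ids: list


# ---------------------------------------------------------------------------
# genome / transcript scaffolding
# ---------------------------------------------------------------------------

_UTR5, _CDS, _UTR3, _GAP = 30, 300, 30, 50


def _build_genome(panel, rng):
    """One chromosome; genes laid out left to right, each UTR5+CDS+UTR3."""
    chrom = "chr1"
    pieces, models, cursor = [], [], 1
    for spec in panel:
        gene_len = _UTR5 + _CDS + _UTR3
        seq = rng.choice(_BASES, size=gene_len + _GAP)
        # avoid premature stops being overwhelmingly likely: no constraint needed,
        # effects are classified per-codon, a stop in the reference is harmless
        pieces.append("".join(seq))
        utr5 = (cursor, cursor + _UTR5 - 1)
        cds = (cursor + _UTR5, cursor + _UTR5 + _CDS - 1)
        utr3 = (cds[1] + 1, cds[1] + _UTR3)
        models.append(
            TranscriptModel(
                gene=spec.gene, chrom=chrom, strand="+",
                cds_intervals=[cds], utr5_intervals=[utr5], utr3_intervals=[utr3],
            )
        )
        cursor += gene_len + _GAP
    reference = {chrom: "".join(pieces)}
    for m in models:
        attach_reference(m, reference)
    return reference, models


def _random_alt(ref_base, rng):
    choices = [b for b in "ACGT" if b != ref_base]
    return choices[int(rng.integers(len(choices)))]


def _aa_change_label(model, reference, pos, alt):
    cds_pos = model.cds_positions()
    idx = cds_pos.index(pos)
    codon_i = idx // 3
    cds = model.cds_sequence(reference)
    codon = list(cds[codon_i * 3 : codon_i * 3 + 3])
    ref_aa = GENETIC_CODE["".join(codon)]
    codon[idx % 3] = alt
    alt_aa = GENETIC_CODE["".join(codon)]
    return f"{ref_aa}{codon_i + 1}{alt_aa if alt_aa != '*' else '*'}"


def _make_record(sample, chrom, pos, ref, alt, vaf, depth, model=None,
                 reference=None, aa=True):
    depth = int(depth)
    alt_depth = int(min(depth, math.floor(vaf * depth)))
    obs_vaf = alt_depth / depth if depth > 0 else 0.0
    rec = VariantRecord(
        sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
        vaf=obs_vaf, depth=depth, alt_depth=alt_depth,
    )
    if model is not None:
        rec.gene = model.gene
        rec.functional_class = classify_effect(rec, model)
        if aa and rec.is_snv and rec.functional_class in (
            FunctionalClass.MISSENSE, FunctionalClass.NONSENSE, FunctionalClass.SYNONYMOUS
        ):
            rec.aa_change = _aa_change_label(model, reference, pos, alt)
    return rec


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def _censor_scale(lam: float, target: float) -> float:
    """Upper bound c of U(0, c) censoring achieving P(censored) = target for
    an Exponential(lam) event time."""
    if target <= 0:
        return float("inf")

    def frac_censored(c):
        return (1.0 - math.exp(-lam * c)) / (lam * c) - target

    return brentq(frac_censored, 1e-9, 1e9 / lam)


def simulate_survival(
    log_hazards: Sequence[float],
    params: SimulationParams,
    rng: np.random.Generator,
):
    """Exponential proportional-hazards times with independent uniform
    censoring calibrated per subject to the target censoring fraction.

    Returns (os_months, os_event) arrays; times are truncated at
    max_followup_months (truncation counts as censoring).
    """
    if params.baseline_hazard <= 0:
        raise ValueError("hazard must be positive")
    times, events = [], []
    for lh in log_hazards:
        lam = params.baseline_hazard * math.exp(lh)
        t = rng.exponential(1.0 / lam)
        if params.censoring_fraction > 0:
            c = min(rng.uniform(0, _censor_scale(lam, params.censoring_fraction)),
                    params.max_followup_months)
        else:
            c = params.max_followup_months
        if t <= c:
            times.append(max(t, 0.01))
            events.append(True)
        else:
            times.append(max(c, 0.01))
            events.append(False)
    return np.array(times), np.array(events, dtype=bool)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(params: SimulationParams) -> SimulationBundle:
    """Generate the full bundle; byte-identical given the same params/seed."""
    rng = np.random.default_rng(params.seed)
    panel = list(params.gene_panel)
    reference, models = _build_genome(panel, rng)
    chrom = "chr1"
    model_by_gene = {m.gene: m for m in models}
    spec_by_gene = {g.gene: g for g in panel}
    sample_ids = [f"S{i + 1:04d}" for i in range(params.n_samples)]

    # --- pools -------------------------------------------------------------
    cds_positions = []
    for m in models:
        cds_positions.extend((m.gene, p) for p in m.cds_positions())
    all_positions = []
    for m in models:
        s, e = m.span()
        all_positions.extend((m.gene, p) for p in range(s, e + 1))

    used = set()

    def _draw_site(pool):
        for _ in range(10000):
            gene, pos = pool[int(rng.integers(len(pool)))]
            if pos not in used:
                used.add(pos)
                return gene, pos
        raise RuntimeError("site pool exhausted")

    # germline SNP pool -> SNP database (common flag set)
    snp_pool = []
    for _ in range(params.n_snp_pool):
        gene, pos = _draw_site(all_positions)
        ref = reference[chrom][pos - 1]
        snp_pool.append((gene, pos, ref, _random_alt(ref, rng)))

    # hotspot pool: recurrent somatic keys, mostly catalogued
    hotspots = []
    onc_cds = [gp for gp in cds_positions if spec_by_gene[gp[0]].role == "oncogene"]
    for _ in range(params.n_hotspots):
        gene, pos = _draw_site(onc_cds or cds_positions)
        ref = reference[chrom][pos - 1]
        hotspots.append((gene, pos, ref, _random_alt(ref, rng)))

    # editing pool: A>G / T>C sites
    editing_pool = []
    at_sites = [(g, p) for g, p in all_positions
                if reference[chrom][p - 1] in "AT" and p not in used]
    for _ in range(min(params.n_editing_pool, len(at_sites))):
        gene, pos = _draw_site(at_sites)
        ref = reference[chrom][pos - 1]
        editing_pool.append((gene, pos, ref, "G" if ref == "A" else "C"))

    # recurrent artifact pool (library/sequencing artifacts shared across samples)
    artifact_pool = []
    for _ in range(params.n_recurrent_artifacts):
        gene, pos = _draw_site(all_positions)
        ref = reference[chrom][pos - 1]
        artifact_pool.append((gene, pos, ref, _random_alt(ref, rng)))

    # --- expression --------------------------------------------------------
    expr = pd.DataFrame(
        {
            s: [spec.expression * rng.lognormal(0.0, 0.25) for spec in panel]
            for s in sample_ids
        },
        index=[spec.gene for spec in panel],
    )

    # --- per-sample variants ----------------------------------------------
    rna_calls, dna_somatic, dna_germline = [], [], []
    truth_rows = []
    depth_tracks = {}
    mutated_nonsyn: dict = {s: set() for s in sample_ids}

    def _rna_depth(sample, gene):
        lam = expr.loc[gene, sample] * params.size_factor
        return int(rng.poisson(lam))

    for sample in sample_ids:
        # depth track: one interval per gene at the sample's coverage level
        intervals = []
        gene_depth = {}
        for m in models:
            s0, e0 = m.span()
            d = _rna_depth(sample, m.gene)
            gene_depth[m.gene] = d
            intervals.append((chrom, s0 - 1, e0, d))
        depth_tracks[sample] = DepthTrack(sample_id=sample, intervals=intervals)

        def _emit_rna(rec, label):
            if rec.depth <= 0 or rec.alt_depth < params.caller_min_alt_depth:
                return
            if rec.vaf < params.caller_min_vaf:
                return
            rna_calls.append(rec)
            truth_rows.append({
                "sample_id": sample, "chrom": rec.chrom, "pos": rec.pos,
                "ref": rec.ref, "alt": rec.alt, "label": label,
            })

        # somatic
        n_som = rng.poisson(params.somatic_rate)
        for _ in range(n_som):
            if hotspots and rng.random() < params.hotspot_fraction:
                gene, pos, ref, alt = hotspots[int(rng.integers(len(hotspots)))]
            else:
                gene, pos = cds_positions[int(rng.integers(len(cds_positions)))]
                ref = reference[chrom][pos - 1]
                alt = _random_alt(ref, rng)
            model = model_by_gene[gene]
            vaf = rng.beta(params.somatic_vaf_alpha, params.somatic_vaf_beta)
            dna_rec = _make_record(sample, chrom, pos, ref, alt,
                                   max(vaf, 0.06), int(rng.poisson(params.dna_depth)) + 10,
                                   model=model, reference=reference)
            dna_somatic.append(dna_rec)
            truncating = dna_rec.functional_class in (
                FunctionalClass.NONSENSE, FunctionalClass.FRAMESHIFT
            )
            if (truncating and spec_by_gene[gene].role == "tumor_suppressor"
                    and rng.random() < params.nmd_dropout):
                continue  # lost from RNA by NMD, retained in DNA truth
            depth = _rna_depth(sample, gene)
            rna = _make_record(sample, chrom, pos, ref, alt, vaf, depth,
                               model=model, reference=reference)
            if rna.functional_class in (
                FunctionalClass.MISSENSE, FunctionalClass.NONSENSE,
                FunctionalClass.SPLICING, FunctionalClass.FRAMESHIFT,
                FunctionalClass.INFRAME_INDEL,
            ):
                mutated_nonsyn[sample].add(gene)
            _emit_rna(rna, "somatic")

        # germline
        n_germ = min(rng.poisson(params.germline_rate), len(snp_pool))
        if n_germ and snp_pool:
            idx = rng.choice(len(snp_pool), size=n_germ, replace=False)
            for i in sorted(idx):
                gene, pos, ref, alt = snp_pool[i]
                model = model_by_gene[gene]
                vaf = 1.0 if rng.random() < 0.3 else rng.beta(30, 30)
                dna_germline.append(
                    _make_record(sample, chrom, pos, ref, alt, vaf,
                                 int(rng.poisson(params.dna_depth)) + 10,
                                 model=model, reference=reference)
                )
                depth = _rna_depth(sample, gene)
                _emit_rna(
                    _make_record(sample, chrom, pos, ref, alt, vaf, depth,
                                 model=model, reference=reference),
                    "germline",
                )

        # RNA editing (RNA only, A>G / T>C)
        n_edit = rng.poisson(params.editing_rate)
        for _ in range(min(n_edit, len(editing_pool)) if editing_pool else 0):
            gene, pos, ref, alt = editing_pool[int(rng.integers(len(editing_pool)))]
            depth = _rna_depth(sample, gene)
            vaf = rng.beta(2.5, 5.0)
            _emit_rna(
                _make_record(sample, chrom, pos, ref, alt, vaf, depth,
                             model=model_by_gene[gene], reference=reference),
                "editing",
            )

        # artifacts (RNA only): recurrent, low-VAF, or low-depth signatures
        n_art = rng.poisson(params.artifact_rate)
        for _ in range(n_art):
            u = rng.random()
            if artifact_pool and u < params.recurrent_artifact_fraction:
                gene, pos, ref, alt = artifact_pool[int(rng.integers(len(artifact_pool)))]
                depth = _rna_depth(sample, gene)
                vaf = rng.beta(3, 7)
            elif u < params.recurrent_artifact_fraction + params.low_depth_artifact_fraction:
                gene, pos = all_positions[int(rng.integers(len(all_positions)))]
                ref = reference[chrom][pos - 1]
                alt = _random_alt(ref, rng)
                depth = int(rng.integers(params.caller_min_alt_depth + 2, 8))
                vaf = rng.uniform(0.3, 0.6)
            else:
                gene, pos = all_positions[int(rng.integers(len(all_positions)))]
                ref = reference[chrom][pos - 1]
                alt = _random_alt(ref, rng)
                depth = _rna_depth(sample, gene)
                vaf = rng.uniform(max(params.caller_min_vaf + 0.002, 0.022),
                                  params.artifact_vaf_max - 0.002)
            _emit_rna(
                _make_record(sample, chrom, pos, ref, alt, vaf, depth,
                             model=model_by_gene[gene], reference=reference),
                "artifact",
            )

    # --- panel of normals --------------------------------------------------
    normal_callsets = []
    for j in range(params.n_normals):
        normal = []
        sample = f"N{j + 1:03d}"
        n_germ = min(rng.poisson(params.germline_rate), len(snp_pool))
        if n_germ:
            idx = rng.choice(len(snp_pool), size=n_germ, replace=False)
            for i in sorted(idx):
                gene, pos, ref, alt = snp_pool[i]
                normal.append(_make_record(sample, chrom, pos, ref, alt,
                                           rng.beta(30, 30), 40,
                                           model=model_by_gene[gene], reference=reference))
        for gene, pos, ref, alt in artifact_pool:
            if rng.random() < 0.6:
                normal.append(_make_record(sample, chrom, pos, ref, alt,
                                           rng.beta(3, 7), 40,
                                           model=model_by_gene[gene], reference=reference))
        normal_callsets.append(normal)

    # --- annotation resources ---------------------------------------------
    resources = {
        "dbsnp": pd.DataFrame(
            [{"chrom": chrom, "pos": p, "ref": r, "alt": a, "common": 1}
             for _, p, r, a in snp_pool]
        ),
        "cosmic": pd.DataFrame(
            [{"chrom": chrom, "pos": p, "ref": r, "alt": a,
              "occurrences": int(rng.integers(20, 500))}
             for _, p, r, a in hotspots
             if rng.random() < params.cosmic_hotspot_fraction]
        ),
        "editing": pd.DataFrame(
            [{"chrom": chrom, "pos": p, "change": f"{r}>{a}"}
             for _, p, r, a in editing_pool
             if rng.random() < params.editing_db_coverage]
        ),
        "clinicaldb": pd.DataFrame(
            [{"chrom": chrom, "pos": p, "ref": r, "alt": a}
             for _, p, r, a in hotspots
             if rng.random() < params.clinical_db_fraction]
        ),
        "popaf_gnomad": pd.DataFrame(
            [{"chrom": chrom, "pos": p, "ref": r, "alt": a,
              "af": float(np.round(rng.uniform(0.01, 0.5), 4))}
             for _, p, r, a in snp_pool]
        ),
        "popaf_swegen": pd.DataFrame(
            [{"chrom": chrom, "pos": p, "ref": r, "alt": a,
              "af": float(np.round(rng.uniform(0.01, 0.5), 4))}
             for _, p, r, a in snp_pool if rng.random() < 0.7]
        ),
        "lowcomplexity": [(chrom, 0, 5)],  # leading gap only; genes start at 1
        "druggable_genes": sorted(
            spec.gene for spec in panel if spec.role == "oncogene"
        ),
        "driver_genes": sorted(
            spec.gene for spec in panel if spec.role != "neutral"
        ),
    }

    # --- gene sets ----------------------------------------------------------
    genes = [spec.gene for spec in panel]
    half = max(1, len(genes) // 2)
    gene_sets = [
        GeneSet(name="PATH_A", pathway_id="R-SIM-0001", genes=frozenset(genes[:half])),
        GeneSet(name="PATH_B", pathway_id="R-SIM-0002", genes=frozenset(genes[half:])),
        GeneSet(name="PATH_ONC", pathway_id="R-SIM-0003",
                genes=frozenset(g.gene for g in panel if g.role == "oncogene")),
    ]

    # --- clinical + survival -------------------------------------------------
    log_hrs = []
    for sample in sample_ids:
        lh = sum(params.gene_log_hrs.get(g, 0.0) for g in sorted(mutated_nonsyn[sample]))
        log_hrs.append(lh)
    times, events = simulate_survival(log_hrs, params, rng)
    clinical = []
    for i, sample in enumerate(sample_ids):
        er = "pos" if rng.random() < 0.85 else "neg"
        pgr = "pos" if (er == "pos" and rng.random() < 0.9) else ("pos" if rng.random() < 0.2 else "neg")
        her2 = "pos" if rng.random() < 0.13 else "neg"
        endo = er == "pos" and rng.random() < 0.8
        chemo = rng.random() < 0.3
        her2_rx = her2 == "pos" and rng.random() < 0.8
        clinical.append(ClinicalRecord(
            sample_id=sample,
            age_years=float(np.round(rng.normal(62, 11), 1)),
            tumor_size_mm=float(np.round(rng.lognormal(2.9, 0.4), 1)),
            n_positive_nodes=int(rng.poisson(1.2)),
            histology=["ductal", "lobular", "other"][
                int(rng.choice(3, p=[0.8, 0.12, 0.08]))],
            er_status=er, pgr_status=pgr, her2_status=her2,
            ki67_status=["pos", "neg", "missing"][int(rng.choice(3, p=[0.3, 0.2, 0.5]))],
            nhg=["G1", "G2", "G3"][int(rng.choice(3, p=[0.15, 0.47, 0.38]))],
            pam50=["LumA", "LumB", "HER2E", "Basal", "Normal", "Unclassified"][
                int(rng.choice(6, p=[0.48, 0.28, 0.09, 0.10, 0.03, 0.02]))],
            rx_endocrine=bool(endo), rx_chemo=bool(chemo), rx_her2=bool(her2_rx),
            os_months=float(np.round(times[i], 2)),
            os_event=bool(events[i]),
        ))

    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "chrom", "pos", "ref", "alt", "label"]
    )
    return SimulationBundle(
        params=params, reference=reference, transcript_models=models,
        rna_calls=rna_calls, dna_somatic=dna_somatic, dna_germline=dna_germline,
        normal_callsets=normal_callsets, truth=truth, depth_tracks=depth_tracks,
        expression=expr, clinical=clinical, resources=resources,
        gene_sets=gene_sets, sample_ids=sample_ids,
    )


def bundle_index(bundle: SimulationBundle):
    """Build an in-memory :class:`~rnasomatic.annotate.AnnotationIndex` from a
    bundle's resource payloads (equivalent to writing + reloading the TSVs)."""
    from .annotate import AnnotationIndex, IntervalSet, build_panel_of_normals

    res = bundle.resources

    def _keys(df, value=None, cast=None):
        out = {}
        for r in df.itertuples(index=False):
            out[(r.chrom, int(r.pos), r.ref, r.alt)] = (
                cast(getattr(r, value)) if value else None
            )
        return out

    pon = build_panel_of_normals(bundle.normal_callsets) if bundle.normal_callsets else set()
    return AnnotationIndex(
        dbsnp={k: bool(v) for k, v in _keys(res["dbsnp"], "common", int).items()},
        cosmic=_keys(res["cosmic"], "occurrences", int) if len(res["cosmic"]) else {},
        population_af={
            "gnomad": _keys(res["popaf_gnomad"], "af", float),
            "swegen": _keys(res["popaf_swegen"], "af", float),
        },
        editing_sites={(r.chrom, int(r.pos), r.change)
                       for r in res["editing"].itertuples(index=False)},
        low_complexity=IntervalSet(res["lowcomplexity"]),
        clinical_db=set(_keys(res["clinicaldb"])) if len(res["clinicaldb"]) else set(),
        pon=pon,
        druggable_genes=frozenset(res["druggable_genes"]),
        driver_genes=frozenset(res["driver_genes"]),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_bundle(bundle: SimulationBundle, outdir) -> None:
    """Write the directory layout every CLI subcommand consumes (text only)."""
    out = Path(outdir)
    for sub in ("rna", "dna_somatic", "dna_germline", "normals", "tracks", "resources"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    with open(out / "reference.fa", "w") as fh:
        for chrom, seq in bundle.reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    contigs = sorted(bundle.reference)

    def _by_sample(records):
        d = {}
        for r in records:
            d.setdefault(r.sample_id, []).append(r)
        return d

    for name, records in (("rna", bundle.rna_calls),
                          ("dna_somatic", bundle.dna_somatic),
                          ("dna_germline", bundle.dna_germline)):
        per = _by_sample(records)
        for sample in bundle.sample_ids:
            path = out / name / f"{sample}.vcf"
            if per.get(sample):
                write_vcf(path, per[sample], contigs=contigs)
            else:
                _write_empty_vcf(path, sample, contigs)
    for i, callset in enumerate(bundle.normal_callsets):
        sample = f"N{i + 1:03d}"
        if callset:
            write_vcf(out / "normals" / f"{sample}.vcf", callset, contigs=contigs)
        else:
            _write_empty_vcf(out / "normals" / f"{sample}.vcf", sample, contigs)

    for sample, track in bundle.depth_tracks.items():
        write_bed(out / "tracks" / f"{sample}.bed", track.intervals)

    bundle.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    bundle.expression.to_csv(out / "expression.tsv", sep="\t", index_label="gene")
    write_clinical(out / "clinical.tsv", bundle.clinical)
    write_gene_sets(out / "pathways.gmt", bundle.gene_sets)

    res = out / "resources"
    for name in ("dbsnp", "cosmic", "editing", "clinicaldb", "popaf_gnomad", "popaf_swegen"):
        bundle.resources[name].to_csv(res / f"{name}.tsv", sep="\t", index=False)
    write_bed(res / "lowcomplexity.bed", bundle.resources["lowcomplexity"])
    (res / "druggable_genes.txt").write_text(
        "\n".join(bundle.resources["druggable_genes"]) + "\n")
    (res / "driver_genes.txt").write_text(
        "\n".join(bundle.resources["driver_genes"]) + "\n")
    # panel of normals as keyed TSV
    from .annotate import build_panel_of_normals

    pon = build_panel_of_normals(bundle.normal_callsets) if bundle.normal_callsets else set()
    pd.DataFrame(
        [{"chrom": c, "pos": p, "ref": r, "alt": a} for c, p, r, a in sorted(pon)]
    ).to_csv(res / "pon.tsv", sep="\t", index=False)


def _write_empty_vcf(path, sample, contigs):
    # write_vcf derives the sample name from records; build the header by hand
    import pysam

    header = pysam.VariantHeader()
    for chrom in contigs:
        header.contigs.add(chrom)
    from .io_core import VCF_HEADER_LINES

    for kind, tag, number, vtype, desc in VCF_HEADER_LINES:
        header.add_meta(kind, items=[("ID", tag), ("Number", number),
                                     ("Type", vtype), ("Description", desc)])
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header):
        pass
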
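"""Self-contained synthetic screen generation with known ground truth.

Everything downstream modules consume — genome FASTA, gene models, guide
library, FASTQ reads, residue annotation tables, toy PDB structures — can
be generated here from a seed, together with truth tables recording every
planted intermediate (true fold changes, residue effect profiles, hit
genes).  The planted effect model mirrors the associations a dense
mutagenesis screen is expected to show: residues that are conserved
(negative PROVEAN), ordered, and inside a domain carry stronger effects,
so association tests on generated data have a known sign.

Also houses the diploid editing-outcome simulator: with two independently
repaired alleles and a per-allele frameshift probability p, a fraction p^2
of edited cells acquires a biallelic frameshift (complete loss of
function) and 1 - p^2 retains at least one in-frame allele.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gene_models import (
    GeneModel,
    GuideRecord,
    Transcript,
    enumerate_guides,
    guides_to_frame,
    mrna_features,
    reverse_complement,
)

__all__ = [
    "GeneSpec",
    "FixtureConfig",
    "ScreenFixture",
    "generate_screen",
    "simulate_biallelic_outcomes",
    "make_prediction_fixture",
    "make_toy_pdb",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODON_TABLE = None

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(cds).translate(to_stop=False))


@dataclass
class GeneSpec:
    """Planted properties of one synthetic gene."""

    gene_id: str
    protein_length: int = 150
    n_exons: int = 3
    strand: str = "+"
    hit_strength: float = 0.0  # planted log2FC scale; 0 = neutral gene


@dataclass
class FixtureConfig:
    """Study conditions of a generated tiling screen.

    Defaults describe a desk-scale two-gene fitness screen: one strong
    negative hit and one neutral gene, ~40 guides per gene, two replicate
    samples per arm at 100k reads, biological noise sd 0.3 log2 units.
    """

    genes: list[GeneSpec] = field(default_factory=lambda: [
        GeneSpec("GENE_A", hit_strength=-3.0, strand="+"),
        GeneSpec("GENE_B", hit_strength=0.0, strand="-"),
    ])
    guides_per_gene: int = 40
    n_control_guides: int = 50
    read_depth: int = 100_000
    noise_sd: float = 0.3
    n_replicates: int = 2
    # planted effect-profile weights: conservation, order, domain offset
    w_conservation: float = 0.4
    w_order: float = 0.3
    domain_offset: float = 0.3
    frameshift_prob: float = 2.0 / 3.0
    low_offtarget_fraction: float = 0.05
    seed: int = 0


@dataclass
class ScreenFixture:
    """In-memory handle to a generated screen plus its truth tables."""

    config: FixtureConfig
    genome: dict[str, str]
    gene_models: dict[str, GeneModel]
    proteins: dict[str, str]
    codons: dict[str, list[str]]
    guides: pd.DataFrame          # library incl. controls
    counts: pd.DataFrame          # guide x sample true counts
    truth_guides: pd.DataFrame    # planted per-guide log2FC
    truth_residues: pd.DataFrame  # planted per-residue annotations/effects
    truth_genes: pd.DataFrame     # planted hit status
    provean: dict[str, np.ndarray]
    disorder: dict[str, np.ndarray]
    ss_tables: dict[str, list[pd.DataFrame]]
    domains: dict[str, list[tuple[int, int, str]]]
    comparisons: dict[str, tuple[list[str], list[str]]]
    paths: dict[str, str] = field(default_factory=dict)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random coding sequence: ATG + internal codons (no stops) + TAA.

    Nucleotides are GC-biased (30% G, 30% C) so PAM density supports dense
    guide coverage.
    """
    nts = np.array(list("ACGT"))
    p = np.array([0.2, 0.3, 0.3, 0.2])
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(nts, size=3, p=p))
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _build_gene(rng: np.random.Generator, spec: GeneSpec):
    """Lay a gene on its own contig: flank exon1 intron ... exonN flank."""
    L = spec.protein_length
    cds = _random_cds(rng, L + 1)  # stop codon included
    cds_len = len(cds)
    n_exons = max(1, spec.n_exons)
    # split the CDS into n_exons chunks, each at least 20 nt
    cuts = sorted(rng.choice(
        np.arange(20, cds_len - 20), size=n_exons - 1, replace=False
    )) if n_exons > 1 else []
    bounds = [0, *cuts, cds_len]
    flank = "".join(rng.choice(list("ACGT"), size=60))
    pieces, cds_ivs = [flank], []
    pos = len(flank)
    for i in range(n_exons):
        chunk = cds[bounds[i]:bounds[i + 1]]
        pieces.append(chunk)
        cds_ivs.append((pos, pos + len(chunk)))
        pos += len(chunk)
        if i < n_exons - 1:
            intron = "GT" + "".join(rng.choice(list("ACT"), size=56)) + "AG"
            pieces.append(intron)
            pos += len(intron)
    pieces.append("".join(rng.choice(list("ACGT"), size=60)))
    sense = "".join(pieces)
    if spec.strand == "-":
        contig_seq = reverse_complement(sense)
        n = len(sense)
        cds_ivs = sorted((n - b, n - a) for a, b in cds_ivs)
    else:
        contig_seq = sense
    tx = Transcript(f"{spec.gene_id}_T1", exons=list(cds_ivs), cds=list(cds_ivs))
    model = GeneModel(
        gene_id=spec.gene_id,
        contig=f"ctg_{spec.gene_id}",
        strand=spec.strand,
        transcripts=[tx],
        principal_transcript_id=tx.transcript_id,
    )
    protein = _translate(cds)[:-1]  # drop stop '*'
    codons = [cds[i:i + 3] for i in range(0, cds_len - 3, 3)]
    return contig_seq, model, protein, codons


def _plant_annotations(rng: np.random.Generator, L: int):
    """Per-residue PROVEAN, disorder, domain interval, and SS tables.

    One central domain covers ~40% of the protein: conserved (PROVEAN
    around -8), ordered (low disorder), helical; outside is weakly
    conserved, disordered, coil.
    """
    dom_len = max(10, int(0.4 * L))
    dom_start = int(rng.integers(5, L - dom_len - 4))
    in_dom = np.zeros(L, bool)
    in_dom[dom_start - 1 : dom_start - 1 + dom_len] = True
    provean = np.where(
        in_dom, rng.normal(-8.0, 1.5, L), rng.normal(-2.0, 1.2, L)
    )
    disorder = np.clip(
        np.where(in_dom, rng.beta(2, 8, L), rng.beta(8, 3, L)), 0, 1
    )
    tables = []
    for _ in range(2):  # two synthetic secondary-structure predictors
        h = np.where(in_dom, rng.uniform(0.6, 0.9, L), rng.uniform(0.0, 0.2, L))
        b = rng.uniform(0.0, 0.1, L)
        c = np.clip(1 - h - b, 0, None)
        tot = h + b + c
        tables.append(pd.DataFrame({"H": h / tot, "B": b / tot, "C": c / tot}))
    domain = (dom_start, dom_start + dom_len - 1, "DOM1")
    return provean, disorder, [domain], tables, in_dom


def _random_spacer(rng: np.random.Generator, taboo: set[str]) -> str:
    while True:
        s = "".join(rng.choice(list("ACGT"), size=20))
        if s not in taboo:
            return s


def generate_screen(
    config: FixtureConfig, out_dir: str | None = None
) -> ScreenFixture:
    """Generate a complete synthetic tiling screen with ground truth.

    Writes (when ``out_dir`` is given) genome FASTA, GFF3 gene models, the
    guide library TSV, one FASTQ per sample, annotation TSVs and truth
    tables; the same objects are returned in memory.  Reproducible: one
    config+seed gives byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    genome: dict[str, str] = {}
    models: dict[str, GeneModel] = {}
    proteins: dict[str, str] = {}
    codons: dict[str, list[str]] = {}
    provean: dict[str, np.ndarray] = {}
    disorder: dict[str, np.ndarray] = {}
    ss_tables: dict[str, list[pd.DataFrame]] = {}
    domains: dict[str, list[tuple[int, int, str]]] = {}

    guide_frames = []
    res_rows = []
    gene_rows = []
    for spec in config.genes:
        contig_seq, model, protein, gene_codons = _build_gene(rng, spec)
        genome[model.contig] = contig_seq
        models[spec.gene_id] = model
        proteins[spec.gene_id] = protein
        codons[spec.gene_id] = gene_codons
        L = spec.protein_length
        pv, dis, doms, sst, in_dom = _plant_annotations(rng, L)
        provean[spec.gene_id] = pv
        disorder[spec.gene_id] = dis
        domains[spec.gene_id] = doms
        ss_tables[spec.gene_id] = sst

        # planted effect profile in [0, 1]
        cons = (-pv - (-pv).min()) / max((-pv).max() - (-pv).min(), 1e-12)
        order = 1.0 - dis
        prof = (config.w_conservation * cons + config.w_order * order
                + config.domain_offset * in_dom)
        prof = (prof - prof.min()) / max(prof.max() - prof.min(), 1e-12)

        all_guides = enumerate_guides(genome, model)
        if len(all_guides) < config.guides_per_gene:
            raise ValueError(
                f"infeasible config: {spec.gene_id} has only "
                f"{len(all_guides)} candidate guides "
                f"(requested {config.guides_per_gene})"
            )
        pick = sorted(rng.choice(len(all_guides), size=config.guides_per_gene,
                                 replace=False))
        chosen = [all_guides[i] for i in pick]
        for g in chosen:
            g.offtarget_score = float(rng.uniform(20, 100))
            g.efficiency_score = float(rng.beta(2, 2))
            g.mrna = mrna_features(g, model)
        n_low = int(round(config.low_offtarget_fraction * len(chosen)))
        for i in rng.choice(len(chosen), size=n_low, replace=False):
            chosen[i].offtarget_score = float(rng.uniform(0, 5))
        gdf = guides_to_frame(chosen)
        eff = prof[[int(round((a1 + a2) / 2)) - 1
                    for a1, a2 in zip(gdf["aa1"], gdf["aa2"])]]
        gdf["true_lfc"] = np.where(
            spec.hit_strength != 0,
            spec.hit_strength * (0.5 + 0.5 * eff),
            0.0,
        ) + rng.normal(0, config.noise_sd, len(gdf))
        guide_frames.append(gdf)
        for r in range(L):
            res_rows.append({
                "gene_id": spec.gene_id, "position": r + 1,
                "provean": pv[r], "disorder": dis[r],
                "in_domain": bool(in_dom[r]), "effect_profile": prof[r],
            })
        gene_rows.append({
            "gene_id": spec.gene_id, "hit_strength": spec.hit_strength,
            "true_hit": spec.hit_strength != 0,
            "direction": ("negative" if spec.hit_strength < 0 else
                          "positive" if spec.hit_strength > 0 else "none"),
            "protein_length": L, "n_guides": config.guides_per_gene,
        })

    guides = pd.concat(guide_frames, ignore_index=True)
    taboo = set(guides["spacer"])
    ctrl_rows = []
    for i in range(config.n_control_guides):
        sp = _random_spacer(rng, taboo)
        taboo.add(sp)
        ctrl_rows.append({
            "guide_id": f"ctrl_{i + 1}", "gene_id": None, "spacer": sp,
            "pam": "NGG", "contig": None, "strand": None, "cut_coord": None,
            "aa1": None, "aa2": None,
            "offtarget_score": float(rng.uniform(50, 100)),
            "efficiency_score": float(rng.beta(2, 2)),
            "true_lfc": rng.normal(0, config.noise_sd),
        })
    guides = pd.concat([guides, pd.DataFrame(ctrl_rows)], ignore_index=True)

    # counts: control-arm abundance lognormal; test-arm scaled by 2^lfc
    n_guides = len(guides)
    abundance = rng.lognormal(0.0, 0.3, n_guides)
    lfc = guides["true_lfc"].to_numpy(float)
    test_w = abundance * np.power(2.0, lfc)
    counts = {}
    samples_ctrl, samples_test = [], []
    for r in range(1, config.n_replicates + 1):
        s = f"plasmid_rep{r}"
        counts[s] = rng.poisson(config.read_depth * abundance / abundance.sum())
        samples_ctrl.append(s)
    for r in range(1, config.n_replicates + 1):
        s = f"final_rep{r}"
        counts[s] = rng.poisson(config.read_depth * test_w / test_w.sum())
        samples_test.append(s)
    count_df = pd.DataFrame(counts, index=guides["guide_id"])
    comparisons = {"fitness": (samples_test, samples_ctrl)}

    truth_guides = guides[["guide_id", "gene_id", "spacer", "cut_coord",
                           "aa1", "aa2", "true_lfc"]].copy()
    truth_residues = pd.DataFrame(res_rows)
    truth_genes = pd.DataFrame(gene_rows)

    fx = ScreenFixture(
        config=config, genome=genome, gene_models=models, proteins=proteins,
        codons=codons, guides=guides, counts=count_df,
        truth_guides=truth_guides, truth_residues=truth_residues,
        truth_genes=truth_genes, provean=provean, disorder=disorder,
        ss_tables=ss_tables, domains=domains, comparisons=comparisons,
    )
    if out_dir is not None:
        _write_fixture(fx, out_dir)
    return fx


def _write_fixture(fx: ScreenFixture, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    p = fx.paths
    p["fasta"] = os.path.join(out_dir, "genome.fa")
    with open(p["fasta"], "w") as fh:
        for contig, seq in fx.genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    p["gff3"] = os.path.join(out_dir, "genes.gff3")
    with open(p["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, model in fx.gene_models.items():
            tx = model.principal
            lo = min(a for a, _ in tx.exons) + 1
            hi = max(b for _, b in tx.exons)
            fh.write(f"{model.contig}\tsyn\tgene\t{lo}\t{hi}\t.\t"
                     f"{model.strand}\t.\tID={gid}\n")
            fh.write(f"{model.contig}\tsyn\tmRNA\t{lo}\t{hi}\t.\t"
                     f"{model.strand}\t.\tID={tx.transcript_id};"
                     f"Parent={gid};principal=1\n")
            for a, b in tx.exons:
                fh.write(f"{model.contig}\tsyn\texon\t{a + 1}\t{b}\t.\t"
                         f"{model.strand}\t.\tParent={tx.transcript_id}\n")
            for a, b in tx.cds:
                fh.write(f"{model.contig}\tsyn\tCDS\t{a + 1}\t{b}\t.\t"
                         f"{model.strand}\t0\tParent={tx.transcript_id}\n")
    p["library"] = os.path.join(out_dir, "library.tsv")
    fx.guides.to_csv(p["library"], sep="\t", index=False)
    for sample in fx.counts.columns:
        path = os.path.join(out_dir, f"{sample}.fastq")
        p[f"fastq_{sample}"] = path
        with open(path, "w") as fh:
            i = 0
            for gid, n in fx.counts[sample].items():
                spacer = fx.guides.set_index("guide_id").loc[gid, "spacer"]
                for _ in range(int(n)):
                    i += 1
                    fh.write(f"@read_{i}\n{spacer}\n+\n{'I' * len(spacer)}\n")
    for name, data in (("provean", fx.provean), ("disorder", fx.disorder)):
        path = os.path.join(out_dir, f"{name}.tsv")
        p[name] = path
        rows = []
        for gid, arr in data.items():
            for i, v in enumerate(arr):
                rows.append({"protein_id": gid, "position": i + 1, name: v})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    p["domains"] = os.path.join(out_dir, "domains.tsv")
    rows = [
        {"protein_id": gid, "start": a, "end": b, "domain_id": d,
         "source": "synthetic"}
        for gid, doms in fx.domains.items() for a, b, d in doms
    ]
    pd.DataFrame(rows).to_csv(p["domains"], sep="\t", index=False)
    for gid, tables in fx.ss_tables.items():
        for t, tab in enumerate(tables):
            path = os.path.join(out_dir, f"ss_{gid}_tool{t + 1}.tsv")
            p[f"ss_{gid}_tool{t + 1}"] = path
            out = tab.copy()
            out.insert(0, "position", np.arange(1, len(tab) + 1))
            out.insert(0, "protein_id", gid)
            out.to_csv(path, sep="\t", index=False)
    for name, df in (("truth_guides", fx.truth_guides),
                     ("truth_residues", fx.truth_residues),
                     ("truth_genes", fx.truth_genes)):
        path = os.path.join(out_dir, f"{name}.tsv")
        p[name] = path
        df.to_csv(path, sep="\t", index=False)


def simulate_biallelic_outcomes(
    p_frameshift: float = 2.0 / 3.0,
    n_cells: int = 1_000_000,
    seed: int = 0,
) -> dict[str, float]:
    """Monte-Carlo diploid editing outcomes vs the closed form.

    Each edited cell draws two independent allele repairs, each a
    frameshift with probability ``p_frameshift``.  Returns empirical and
    closed-form fractions of biallelic-frameshift cells (p^2, complete
    loss of function) and cells retaining any in-frame allele (1 - p^2).
    """
    if not 0 <= p_frameshift <= 1:
        raise ValueError("p_frameshift must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    frameshifts = rng.binomial(2, p_frameshift, size=int(n_cells))
    biallelic = float(np.mean(frameshifts == 2))
    return {
        "p_frameshift": p_frameshift,
        "n_cells": int(n_cells),
        "empirical_biallelic_frameshift": biallelic,
        "empirical_any_inframe": 1.0 - biallelic,
        "expected_biallelic_frameshift": p_frameshift ** 2,
        "expected_any_inframe": 1.0 - p_frameshift ** 2,
    }


def make_prediction_fixture(
    n_genes: int = 40,
    guides_per_gene: int = 50,
    noise_sd: float = 0.5,
    seed: int = 7,
) -> pd.DataFrame:
    """Feature-level synthetic screen with a planted predictable signal.

    The scaled score is a noisy function of conservation and disorder of
    the first targeted residue, ``f = -provean1/3 - disorder1``, plus
    Gaussian noise; all other features are uninformative.  Raw per-gene
    scores are reconstructed so that the per-gene target transform
    recovers the planted scaled values (every gene mean is negative, as in
    a dropout screen).  Columns match the feature builder's schema plus
    ``score`` and ``true_scaled``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_genes):
        gene = f"G{g + 1:03d}"
        L = int(rng.integers(200, 600))
        for i in range(guides_per_gene):
            spacer = "".join(rng.choice(list("ACGT"), size=20))
            provean1 = float(rng.normal(-4.0, 2.5))
            provean2 = provean1 + float(rng.normal(0, 0.8))
            disorder1 = float(rng.uniform(0, 1))
            disorder2 = np.clip(disorder1 + rng.normal(0, 0.1), 0, 1)
            aa1 = int(rng.integers(1, L))
            rows.append({
                "guide_id": f"{gene}_g{i + 1}", "gene_id": gene,
                "spacer": spacer,
                "provean1": provean1, "provean2": provean2,
                "disorder1": disorder1, "disorder2": float(disorder2),
                "protein_fraction": aa1 / L,
                "exon_length": int(rng.integers(60, 400)),
                "offtarget_score": float(rng.uniform(20, 100)),
                "dist_5p_exon_border": int(rng.integers(0, 200)),
                "dist_3p_exon_border": int(rng.integers(0, 200)),
                "in_domain": bool(rng.random() < 0.5),
                "exon_multiple_of_3": bool(rng.random() < 0.4),
                "nmd_escape": bool(rng.random() < 0.3),
                "same_strand_as_gene": bool(rng.random() < 0.5),
                "aa1_letter": str(rng.choice(list(AA3))),
                "aa2_letter": str(rng.choice(list(AA3))),
            })
    df = pd.DataFrame(rows)
    signal = -df["provean1"] / 3.0 - df["disorder1"]
    df["true_scaled"] = signal + rng.normal(0, noise_sd, len(df))
    # reconstruct raw dropout scores: negative gene means, sd ~ gene scale
    raw = []
    for gene, grp in df.groupby("gene_id", sort=False):
        s = grp["true_scaled"].to_numpy()
        z = (s - s.mean()) / s.std(ddof=0)
        gene_sd = float(rng.uniform(0.5, 1.5))
        gene_mean = float(rng.uniform(-3.0, -0.5))
        raw.append(pd.Series(-(z * gene_sd) + gene_mean, index=grp.index))
    df["score"] = pd.concat(raw)
    return df


def make_toy_pdb(
    sequence: str,
    path: str,
    chain: str = "A",
    first_resnum: int = 1,
    b_factor: float = 0.0,
) -> None:
    """Write a CA-only toy PDB for a sequence (idealized helix trace).

    A synthetic stand-in structure for testing score-to-structure mapping;
    coordinates are geometric, not physical.
    """
    with open(path, "w") as fh:
        fh.write("REMARK   1 SYNTHETIC CA-ONLY TOY STRUCTURE\n")
        serial = 0
        for i, aa in enumerate(sequence):
            serial += 1
            resnum = first_resnum + i
            theta = i * 100.0 * np.pi / 180.0
            x, y, z = 2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i
            res3 = AA3.get(aa.upper(), "GLY")
            fh.write(
                f"ATOM  {serial:5d}  CA  {res3} {chain}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b_factor:6.2f}"
                f"          {'C':>2s}\n"
            )
        fh.write("TER\nEND\n")
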
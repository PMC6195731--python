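import numpy as np
import pandas as pd
import pytest

import tilescope as ts
from tilescope import annotate, quantify


@pytest.fixture(scope="session")
def screen_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("screen")


@pytest.fixture(scope="session")
def screen(screen_dir):
    """A generated two-gene screen (one planted negative hit, one neutral)
    with files on disk and truth tables in memory."""
    return ts.generate_screen(ts.FixtureConfig(seed=3), out_dir=str(screen_dir))


@pytest.fixture(scope="session")
def scored_guides(screen, screen_dir):
    """Guides with control-normalized functional scores recomputed from the
    generated FASTQ files."""
    lib = dict(zip(screen.guides["spacer"], screen.guides["guide_id"]))
    cols = {}
    for sample in screen.counts.columns:
        col, _ = quantify.count_guides(str(screen_dir / f"{sample}.fastq"), lib)
        cols[sample] = col
    counts = quantify.CountMatrix(pd.DataFrame(cols).loc[screen.counts.index])
    table = quantify.compute_scores(counts, screen.comparisons)
    controls = screen.guides.loc[screen.guides["gene_id"].isna(), "guide_id"]
    table = quantify.normalize_to_controls(table, list(controls))
    df = screen.guides.copy()
    df["score"] = table.scores["fitness"].reindex(df["guide_id"]).to_numpy()
    return df


@pytest.fixture(scope="session")
def annotation_tracks(screen):
    tracks = {}
    for gid, model in screen.gene_models.items():
        L = model.principal.protein_length
        labels, weights = annotate.consensus_secondary_structure(
            screen.ss_tables[gid]
        )
        tracks[gid] = annotate.AnnotationTrack(
            protein_id=gid,
            length=L,
            provean=screen.provean[gid],
            disorder=screen.disorder[gid],
            ss_label=labels,
            ss_weight=weights,
            domains=screen.domains[gid],
            sequence=screen.proteins[gid],
            codons=screen.codons[gid],
        )
    return tracks


@pytest.fixture(scope="session")
def annotated_guides(scored_guides, annotation_tracks):
    targeting = scored_guides.dropna(subset=["gene_id"])
    return annotate.attach_annotations(targeting, annotation_tracks)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
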
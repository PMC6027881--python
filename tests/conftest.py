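"""Shared fixtures: result factories and a small synthetic pipeline run."""

import numpy as np
import pytest

from blastxy import formats, projection, synth
from blastxy.model import PlottedResult


def make_result(**kw) -> PlottedResult:
    """A valid PlottedResult with overridable fields."""
    base = dict(
        x=10.0,
        y=1,
        vector_deg=1.0,
        seg_offset_deg=0.1,
        seg_len_deg=0.5,
        strand="+",
        bitscore=100.0,
        color_value=0.5,
        evalue=1e-20,
        query_id="q1",
        subject_id="s1",
        organism="Synthetica organism",
        product="hypothetical protein",
        replicon_id="rep1",
        s_start=1,
        s_end=100,
    )
    base.update(kw)
    return PlottedResult(**base)


def random_results(rng: np.random.Generator, n: int) -> list:
    """n random-but-valid projected results across a few replicons."""
    out = []
    queries = ["SSI_HlyD", "SSI_TolC", "SSII_GspC", "capA", "capB"]
    organisms = ["Burkholderia_gladioli", "Burkholderia_thailandensis",
                 "Synthetica_minor"]
    for i in range(n):
        vec = float(rng.uniform(0.05, 8.0))
        strand = "+" if rng.random() < 0.5 else "-"
        off = float(rng.uniform(0, vec * 0.5))
        seg = float(rng.uniform(0.01, vec - off))
        y = int(rng.integers(1, 6))
        out.append(
            make_result(
                x=float(rng.uniform(0, 352)),
                y=y,
                vector_deg=vec if strand == "+" else -vec,
                seg_offset_deg=off,
                seg_len_deg=seg,
                strand=strand,
                bitscore=float(np.round(rng.uniform(40, 400), 1)),
                evalue=float(10.0 ** (-rng.uniform(4, 40))),
                query_id=str(rng.choice(queries)),
                subject_id=f"rep{y}_g{i:04d}",
                organism=str(rng.choice(organisms)),
                replicon_id=f"rep{y}",
                s_start=int(rng.integers(1, 50)),
                s_end=int(rng.integers(50, 100)),
            )
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def result_factory():
    return make_result


@pytest.fixture
def random_table(rng):
    return random_results(rng, 200)


@pytest.fixture(scope="session")
def small_genome(tmp_path_factory):
    """Two organisms with chromosome+plasmid, a planted 4-gene cluster."""
    d = tmp_path_factory.mktemp("genome")
    spec = synth.GenomeSimSpec(
        n_organisms=2,
        replicon_lengths=(400_000, 60_000),
        genes_per_replicon=50,
        seed=11,
        organism_names=("Burkholderia_synthetica", "Synthetica_minor"),
        cluster_tags=(
            ("Burkholderia_synthetica_rep1", 10, 4, "capistruin-like"),
        ),
    )
    gff, tsv, replicons, features = synth.generate_genome(spec, str(d))
    return {
        "dir": str(d), "gff": gff, "tsv": tsv,
        "replicons": replicons, "features": features, "spec": spec,
    }


@pytest.fixture(scope="session")
def small_hits(small_genome, tmp_path_factory):
    d = tmp_path_factory.mktemp("hits")
    hspec = synth.HitSimSpec(
        queries=("capA", "capB", "capC", "capD"),
        hit_rate=0.5,
        planted_clusters=(
            synth.PlantedCluster(
                "Burkholderia_synthetica_rep1", 10,
                ("capA", "capB", "capC", "capD"),
            ),
        ),
        seed=13,
    )
    path, n_planted, n_background = synth.simulate_hits(
        small_genome["features"], hspec, str(d / "hits.tsv")
    )
    return {"path": path, "n_planted": n_planted,
            "n_background": n_background, "spec": hspec}


@pytest.fixture(scope="session")
def projected(small_genome, small_hits):
    """The full parse -> join -> project pipeline on the small fixture."""
    hits = formats.read_blast_tabular(small_hits["path"])
    replicons, features = formats.read_annotation(
        small_genome["gff"], small_genome["tsv"]
    )
    replicons = projection.assign_replicon_indices(replicons)
    rows, unresolved = projection.project_hits(hits, features, replicons)
    return {"hits": hits, "replicons": replicons, "features": features,
            "rows": rows, "unresolved": unresolved}
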
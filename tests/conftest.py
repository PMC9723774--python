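import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from mycodiv import CommunityTable, SampleRecord
from mycodiv.core import AM_SPECIES, EM_SPECIES


def make_records(spec):
    """Build SampleRecords from (plot, block, species, richness, comp[, id])."""
    recs = []
    for row in spec:
        plot, block, species, richness, comp = row[:5]
        myc = "AM" if species in AM_SPECIES else "EM"
        short = "".join(w[:2] for w in species.split()[:2])
        sample_id = row[5] if len(row) > 5 else f"{plot}_{short}"
        recs.append(
            SampleRecord(
                sample_id=sample_id,
                plot_id=plot,
                block=block,
                tree_species=species,
                host_myc_type=myc,
                plot_richness=richness,
                plot_myc_composition=comp,
            )
        )
    return recs


@pytest.fixture
def toy_table():
    counts = pd.DataFrame(
        [[3, 0, 1, 0], [0, 2, 5, 0], [1, 1, 0, 4]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
    )
    guilds = {"t1": "AMF", "t2": "AMF", "t3": "EMF", "t4": "EMF"}
    return CommunityTable(counts, guilds)


@pytest.fixture
def toy_tree():
    return TreeNode.read(
        io.StringIO("((a:1,b:2):0.5,((c:1,d:1):0.25,e:2):0.5):0;")
    )


def random_table(rng, n_samples=5, n_taxa=6, guild="AMF"):
    counts = pd.DataFrame(
        rng.integers(0, 20, size=(n_samples, n_taxa)),
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"t{j}" for j in range(n_taxa)],
    )
    return CommunityTable(counts, {f"t{j}": guild for j in range(n_taxa)})


def random_bifurcating_tree(rng, tips):
    """Independent little tree builder used as fixture input (not the
    package's own simulator)."""
    nodes = [TreeNode(name=t) for t in tips]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.uniform(0.01, 1.0))
        b.length = float(rng.uniform(0.01, 1.0))
        nodes.append(TreeNode(children=[a, b]))
    root = nodes[0]
    root.length = None
    return root
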
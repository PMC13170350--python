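import numpy as np
import pandas as pd
import pytest

from lohscan.coverage import CopyTrack
from lohscan.model import Chromosome, GenomeMap, IsolateProfile, TandemArray


@pytest.fixture
def toy_genome():
    """Two chromosomes, evenly spaced SNPs 1 kb apart, one repeat pair."""
    chroms = [
        Chromosome("chrA", 100_000, 45_000, 45_120),
        Chromosome("chrB", 60_000, 30_000, 30_120),
    ]
    rows = []
    for c, n in (("chrA", 100), ("chrB", 60)):
        for i in range(n):
            rows.append({"chrom": c, "pos": 500 + 1000 * i,
                         "allele_P1": "A", "allele_P2": "G"})
    snps = pd.DataFrame(rows)
    features = pd.DataFrame([
        {"track": "repeat", "chrom": "chrA", "start": 20_000, "end": 22_000, "label": "Ty1"},
        {"track": "repeat", "chrom": "chrA", "start": 60_000, "end": 62_000, "label": "Ty1"},
        {"track": "repeat", "chrom": "chrB", "start": 40_000, "end": 42_000, "label": "Ty1"},
        {"track": "snRNA_gene", "chrom": "chrB", "start": 10_000, "end": 10_150,
         "label": "snRNA_gene"},
    ])
    arrays = [TandemArray("rDNA", "chrA", 80_000, 98_000, 9000, 2)]
    return GenomeMap(chroms, snps, features, arrays)


def make_binned_track(genome, states, isolate_id="iso", depth=40):
    """CopyTrack with given per-SNP copy states {chrom: [(c1, c2), ...]}."""
    frames = []
    for c in genome.chromosomes:
        pos = genome.snp_positions(c.name)
        st = states.get(c.name, [(1, 1)] * len(pos))
        assert len(st) == len(pos)
        c1 = np.array([s[0] for s in st])
        c2 = np.array([s[1] for s in st])
        frames.append(pd.DataFrame({
            "chrom": c.name, "pos": pos, "depth_total": depth,
            "rc_P1": c1 / 2.0, "rc_P2": c2 / 2.0,
            "c_P1": c1, "c_P2": c2, "masked": False,
        }))
    data = pd.concat(frames, ignore_index=True)
    return CopyTrack(isolate_id, data, float(depth), {"window": 1})


def make_profile(genome, states=None, depth=40, isolate_id="iso", cycles=8):
    """Noiseless IsolateProfile with depths depth*c/2 from copy states."""
    states = states or {}
    frames = []
    for c in genome.chromosomes:
        pos = genome.snp_positions(c.name)
        st = states.get(c.name, [(1, 1)] * len(pos))
        d1 = [int(round(depth * s[0] / 2)) for s in st]
        d2 = [int(round(depth * s[1] / 2)) for s in st]
        frames.append(pd.DataFrame({"chrom": c.name, "pos": pos,
                                    "depth_P1": d1, "depth_P2": d2}))
    return IsolateProfile(isolate_id, cycles,
                          pd.concat(frames, ignore_index=True))
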
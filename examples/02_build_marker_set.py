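"""Build a marker set: profiles, thresholds, and the retention filters.

Simulates candidate ortholog clusters, applies the retention rules (a
marker must span at least 99% of the reference species and be unambiguous
against every other family's profile), records multi-copy expectations
from a copy-number survey, and saves the bundle as a tar archive of plain
FASTA alignments plus a JSON manifest.
"""

import tempfile

import mycocheck as mc
from mycocheck.markers import Cluster

families = mc.make_marker_families(6, n_members=10, mean_length=120, rng_seed=1)
clusters = [
    Cluster(f.id, tuple(f.members), tuple(f"sp{i:02d}" for i in range(len(f.members))))
    for f in families
]
retained = mc.filter_families(clusters, n_species=10)
print(f"retained {len(retained)} of {len(clusters)} candidate clusters")
for fam in retained[:3]:
    print(
        f"  {fam.id}: threshold {fam.score_threshold:.1f} bits "
        f"(80% of the weakest member self-score {min(fam.member_scores):.1f})"
    )

# a copy-number survey across reference genomes sets multi-copy expectations
survey = {f.id: [1, 1, 1] for f in retained}
survey[retained[0].id] = [2, 3, 2]
mc.set_copy_expectations(retained, survey)
print(f"{retained[0].id} expected in >= {retained[0].expected_min_copies} copies")

markerset = mc.MarkerSet(families={f.id: f for f in retained})
with tempfile.NamedTemporaryFile(suffix=".tar") as tmp:
    mc.save_markerset(markerset, tmp.name)
    reloaded = mc.load_markerset(tmp.name)
print(f"archive round trip: {sorted(reloaded.families) == sorted(markerset.families)}")
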
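"""Normalize gene coverages into average copies per genome.

Ten single-copy marker genes each have aggregate coverage 6, so the marker
median (6) estimates "genomes worth of sequence" in the sample; a TonB-
dependent receptor COG with total coverage 12 then averages 2 copies per
genome, regardless of sequencing depth.
"""

from ironmeta import MarkerSet, build_profile
from ironmeta.functions import OrfFunction, bundled_iron_catalog

markers = MarkerSet.from_iterable([f"M{i}" for i in range(10)])
catalog = bundled_iron_catalog()

coverage = {f"marker_orf{i}": 6.0 for i in range(10)}
functions = {f"marker_orf{i}": OrfFunction(f"marker_orf{i}", f"M{i}") for i in range(10)}
for orf, cov in (("receptor_a", 7.0), ("receptor_b", 5.0), ("regulator", 3.0)):
    coverage[orf] = cov
functions["receptor_a"] = OrfFunction("receptor_a", "COG1629")
functions["receptor_b"] = OrfFunction("receptor_b", "COG1629")
functions["regulator"] = OrfFunction("regulator", "COG0735")

profile = build_profile("june_23", coverage, functions, markers, catalog)
print(f"marker median coverage: {profile.marker_median}")
print(f"COG1629 (ferric siderophore receptor) CN: {profile.cn_by_cog['COG1629']}")
print(f"Fe(III)-OM category CN: {profile.cn_by_category['Fe(III)-OM']}")
print(f"regulators category CN: {profile.cn_by_category['regulators']}")
print()
print(
    "A copy number of 2.0 means the average genome in this community carries "
    "two receptor copies; doubling every coverage would change nothing."
)
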
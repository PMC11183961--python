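"""Run the whole pipeline on a simulated study and summarize what it found.

simulate -> LCA taxonomy -> contig consensus -> COG annotation -> marker
normalization -> category trajectories -> pathway calls, all from one seed.
"""

from ironmeta import default_scenario, run_pipeline

study, report = run_pipeline(default_scenario(seed=1))

bloom = report.fractions_by_rank["phylum"]["Bacteroidetes"]
om = report.cn_by_category["Fe(III)-OM"]
status = report.pathway_status.loc["study"]

print("Recovered Bacteroidetes read fraction: "
      f"{bloom.iloc[0]:.1%} (first sample) -> {bloom.iloc[-1]:.1%} (last sample)")
print(f"Fe(III)-OM transporter copy number:    {om.iloc[0]:.2f} -> {om.iloc[-1]:.2f}")
print(f"Synthesis CN (ambiguity-excluded):     "
      f"{report.synthesis_cn.iloc[0]:.2f} -> {report.synthesis_cn.iloc[-1]:.2f}")
print(f"Pathways PRESENT: {(status == 'PRESENT').sum()}, "
      f"ABSENT: {(status == 'ABSENT').sum()}")
print()
print("Fe(III)-OM breakdown, last sample (who carries the receptors):")
print(report.breakdowns["Fe(III)-OM"].iloc[-1].round(3).to_string())
print()
print(
    "The bloom phylum dominates receptor (consumer) genes while synthesis "
    "stays with the producer clade: the producer/cheater split the simulator "
    "encodes, recovered by the pipeline from noisy tables."
)
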
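"""Run the whole pipeline on synthetic complexes of graded stiffness.

Four synthetic protein-DNA complexes are generated with increasing softness
and increasing Kd; every stage runs per complex and the report correlates
each descriptor with log10(Kd).
"""

from zfdyn.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    complexes=[
        {
            "id": f"SYN{i}",
            "kd_nM": 0.05 * 10**i,  # Kd spans 0.05 nM .. 50 nM
            "synthetic": {
                "n_protein": 12,
                "n_dna": 4,
                "n_frames": 80,
                "flexibility_scale": 2.0 - 0.4 * i,  # tighter binder = softer
            },
        }
        for i in range(4)
    ],
    settings={"seed": 3},
)
report = run_pipeline(config)

for cid, row in report["complexes"].items():
    print(f"{cid}: Kd = {row['kd_nM']:8.3f} nM, "
          f"flexibility = {row['complex_flexibility']:.2f} nm, "
          f"coordination = {row['coordination']:.0f} nm^-2")
print()
for name in ("complex_flexibility", "coordination"):
    stats = report["correlations"][name]
    print(f"r(log10 Kd, {name}) = {stats['r']:+.2f}")
print()
print("Softness was planted to decrease with Kd, so flexibility anticorrelates")
print("with log10(Kd) while coordination (rigidity) correlates positively.")
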
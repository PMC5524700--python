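"""Run the full protocol and map descriptor hotspots back onto residues.

Executes every stage (generate -> align -> grid -> cap -> select -> 120
PLS fits -> rank -> external validation -> metrics -> mapping) on a
desk-scale synthetic study and prints the residues whose atoms sit near
the most activity-correlated grid nodes.
"""

from gridqsar import ProtocolConfig, SyntheticSpec, run_protocol

config = ProtocolConfig(
    synthetic=SyntheticSpec(n_conformations=200, seed=7),  # demo scale
    map_cutoff=0.97, map_radius=2.0,
)
result = run_protocol(config, outdir="scratch_protocol_run")

best = result.best_score
print(f"best model {best.split_id} at |r| threshold "
      f"{result.best_threshold}: q2_test {best.q2_test:.3f}, "
      f"rmse_test {best.rmse_test:.2f}/sec")

ext = result.external_predictions
ext_best = ext[ext.model == best.split_id]
print("\nexternal validation (codes never used for selection or fitting):")
for _, row in ext_best.iterrows():
    print(f"  code {row.code}: predicted {row.predicted_kcat:7.1f}/sec, "
          f"experimental {row.experimental_kcat:7.1f}/sec")

if result.residue_report is not None and len(result.residue_report):
    report = result.residue_report.copy()
    report = report.reindex(
        report.n_ieds.sort_values(ascending=False).index)
    print("\nresidues within 2 A of strongly correlated descriptors "
          "(top 5 by descriptor count):")
    print(report.head(5).to_string(index=False))
# Residues listed here are the candidate activity hotspots: their atoms
# sit next to grid nodes whose probe energies track kcat across variants.
# In this synthetic study the mutated site (residue MUT) should lead.
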
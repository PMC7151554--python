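"""Eukaryote-prokaryote cluster assembly and the exclusivity recheck.

Runs the pipeline on a small dataset and shows the EPC ledger: every linked
eukaryote family is classified bacterial, archaeal, dual (merged, both
prokaryote domains homologous) or ambiguous, and exclusive EPCs are rechecked
against the remaining prokaryotic domain.
"""

import dataclasses

from epclust import PipelineConfig, SimulationConfig, run_pipeline

sim = SimulationConfig(
    n_bacteria=10, genus_sizes=(5, 3, 2), n_archaea=8, n_eukaryotes=6,
    n_euk_bact=6, n_euk_arch=4, n_euk_specific=2, n_euk_dual=2, n_prok_only=1,
    presence_prob={"bacteria": 1.0, "archaea": 1.0, "eukaryote": 1.0},
    seq_length_range=(60, 90),
)
result = run_pipeline(PipelineConfig(simulation=sim, n_replicates=50, seed=5))
m = result.manifest

print(f"eukaryote families: {m.n_families['eukaryote']}  "
      f"(eukaryote-specific: {m.n_euk_specific})")
print(f"EPCs: {m.n_epc} = {m.n_bacterial_only} bacterial-only "
      f"+ {m.n_archaeal_only} archaeal-only + {m.n_dual} dual")
print(f"ambiguous (excluded): {m.n_ambiguous}   "
      f"recheck-excluded: {m.n_recheck_excluded}   final: {m.n_final}")
# The manifest enforces n_epc = bacterial + archaeal + dual and
# n_final = exclusive - recheck-excluded, the same ledger arithmetic the
# full-scale survey reports (2,587 = 1,853 + 515 + 219; 2,368 - 266 = 2,102).
for e in result.epcs[:4]:
    print(f"  {e.epc_id}: origin={e.origin}  euk genomes={len(e.euk_genomes)}  "
          f"prok genomes={len(e.prok_genomes)}")
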
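# data/

Place the study's deposited per-animal c-fos counts here as
`dryad_cfos_counts.csv` to enable the accession-gated acceptance test and
the `scripts/acceptance.py` targets.

Expected format (CSV, header row):

```
animal_id,group,DG,CA3,CA1,BLA,CeA,RSC,IL,PL,Cg1,Cg2,Re,PV
r01,NS,41,23,88,55,30,140,60,72,95,81,38,29
...
```

- `group` ∈ {NS, 2S, 10S}
- one row per animal (8 per group), one column per region
- values are the per-animal mean c-fos+ cell counts (bilateral, ≥2 slices)

Deposit: https://doi.org/10.5061/dryad.280gb5mw3
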
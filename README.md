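# fadskit

Analysis toolkit for functional surveys of teleost fatty acyl desaturases
(Fads2). Teleost fish make docosahexaenoic acid (DHA, 22:6n-3) by one of two
routes: the **Sprecher pathway** (two elongations of EPA to 24:5n-3, a Δ6
desaturation to 24:6n-3, then partial peroxisomal β-oxidation) or the more
direct **Δ4 pathway** (one elongation of EPA to 22:5n-3 followed by Δ4
desaturation). Which route a species can run depends on the regioselectivity
of its Fads2 repertoire, and `fadskit` covers the three computational stages
used to characterise it:

1. **Pathway modelling and assay quantification** (`fadskit.fa`,
   `fadskit.quant`). Fatty acids are parsed from `C:Dn-x` shorthand into
   carboxyl-referenced double-bond positions (methylene-interrupted:
   successive bonds 3 carbons apart), and any substrate/product pair is
   classified as Δk desaturation, elongation, or β-oxidation. Activities in
   heterologous yeast assays are quantified from GC peak areas as

       conversion % = product area / (product area + substrate area) × 100,

   where, along a chained route, the product term of each step includes the
   product's downstream derivatives. Δ6 activity on the C24 Sprecher
   substrate is normalised across enzymes by the ratio
   Δ_24:5n-3 / Δ_control.
2. **Δ4-signature motif scanning** (`fadskit.motifscan`). Functional Δ4
   desaturases carry a conserved region (consensus
   `PPLLIPVFYNFNIMXTMISR`, `X` a wildcard) containing the four-residue
   **YXXN** domain; Y and N at positions 1 and 4 of that domain are required
   for Δ4 activity. The module derives such a consensus from a seed
   alignment, scans candidate proteins by exhaustive wildcard-aware window
   matching, and calls putative Δ4 enzymes by requiring intact anchors plus
   an overall match within a mismatch ceiling.
3. **Distance phylogenetics** (`fadskit.phylo`). p- or Poisson-corrected
   protein distances under pairwise gap deletion, Saitou–Nei neighbor
   joining with deterministic tie-breaking, column-bootstrap supports, and
   Newick I/O — all implemented in-package so runs are bit-reproducible.

`fadskit.synth` provides ground-truth generators (simulated assay peak
tables, protein families evolved along random trees with controllable
signature presence) plus the packaged reference tables, and `fadskit.cli`
wires everything into the `fadskit quantify|scan|tree|simulate` commands.

## Worked example

Rebuild the normalised activity table from the packaged 15-enzyme C24
Δ6-desaturation survey:

```python
import fadskit as fk
from fadskit.quant import report_to_tsv

rows = fk.load_fixture("table1")
reports = fk.build_activity_table([r.record for r in rows])
print(report_to_tsv(reports[:3]))
```

```
desaturase_id	conv_24_4n6	conv_24_5n3	control	conv_control	ratio
ScyΔ6Fads2	29.3	34.3	18:3n-3->18:4n-3	41.9	0.82
AgΔ6Fads2	25.4	19.0	18:3n-3->18:4n-3	15.3	1.24
AjΔ6Fads2	14.0	15.8	18:3n-3->18:4n-3	17.8	0.89
```

Each row shows an enzyme's conversion of the two C24 substrates, its control
conversion, and the normalisation ratio: the catshark enzyme converts
24:5n-3 at 82% of its control-substrate rate (0.82), so it can feed the
Sprecher pathway; Δ4 desaturases sit at 0.00 (no detectable C24 activity).

Simulating the underlying yeast assay with known step fractions and no
noise reproduces the peak areas the formula expects:

```python
table, truth = fk.simulate_assay(
    fk.AssaySimSpec.c24_assay(0.3, 1 / 3, total_substrate_area=1000,
                              noise_cv=0.0))
print(table.areas)
# {'22:5n-3': 700.0, '24:5n-3': 200.0, '24:6n-3': 100.0}
```

i.e. 30% of the substrate was elongated onward (300 of 1000) and one third
of that was Δ6-desaturated — `fk.chain_conversions` recovers exactly 30.0%
and 33.3% from these areas.

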
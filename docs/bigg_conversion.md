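# Converting a BiGG/SBML model to the reaction-table format

`hypercurv` reads metabolic models as a 4-column TSV
(`id<TAB>direction<TAB>reactants<TAB>products`, `direction` ∈
`irrev`/`rev`, species comma-separated, optional integer stoichiometric
coefficients). Model download and SBML parsing are deliberately outside the
package; with `cobrapy` installed the conversion is a few lines.

```python
import cobra

# e.g. the M. tuberculosis model: cobra.io.load_model("iNJ661")
# (downloads from the BiGG database), or cobra.io.read_sbml_model(path)
model = cobra.io.load_model("iNJ661")

with open("data/iNJ661_reactions.tsv", "w") as fh:
    for rxn in model.reactions:
        direction = "rev" if rxn.reversibility else "irrev"
        reactants = ",".join(m.id for m in rxn.reactants)
        products = ",".join(m.id for m in rxn.products)
        fh.write(f"{rxn.id}\t{direction}\t{reactants}\t{products}\n")
```

Notes:

* Use the bare metabolite ids as they appear in the model
  (compartment-suffixed, e.g. `atp_c`); `hypercurv` compares labels by
  exact string equality and applies no namespace normalization. For the
  published statistics the compartment-stripped ids (`atp`) were used;
  strip suffixes with `m.id.rsplit("_", 1)[0]` if you want that convention
  and your model is single-compartment for the species of interest.
* `hypercurv.io_formats.read_reaction_table` performs the reversible split
  (`_f`/`_r`), coefficient dropping, and catalyst retention; do not
  pre-split reactions.
* Place the table at `data/iNJ661_reactions.tsv` under the repository root
  and the genome-scale integration test in `tests/test_acceptance.py` will
  run automatically.
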
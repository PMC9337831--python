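# gatesite

Nomination of **gatekeeper mutation sites** from ligand–protein close-contact
analysis of conformational ensembles.

A gatekeeper mutant is an enzyme variant engineered to resist a specific
inhibitor while keeping its catalytic activity. It is the cleanest way to test
whether a drug's cellular activity is on-target: if the phenotype disappears
in cells expressing the gatekeeper mutant, the drug acts through that enzyme.
`gatesite` implements the in-silico side of designing such a mutant for an
ATP-competitive kinase inhibitor, using as its running example the MERTK
kinase, the inhibitor MRX-2843, and the natural nucleotide ADP.

## Method

The inputs are two conformational ensembles of the same kinase — frames of
the inhibitor-bound and the nucleotide-bound complex, e.g. extracted from MD
trajectories — plus a residue annotation table and a family multiple sequence
alignment. For each frame, every ligand-atom/protein-atom pair with distance
*d* < 4.5 Å counts as one close contact. Summing over frames and grouping by
residue gives a per-residue contact profile; comparing per-frame means
between the two ensembles gives the differential contact
Δ(r) = c̄_inh(r) − c̄_nat(r).

A staged triage then narrows the contacting residues to candidate sites:

1. **proximal** — frame occupancy (fraction of frames with ≥ 1 inhibitor
   contact) ≥ 5 %;
2. **structural_ok** — remove residues contacting the inhibitor mostly via
   backbone atoms (backbone fraction ≥ 0.75; a side-chain substitution cannot
   remove those contacts) and residues annotated critical for structural or
   catalytic integrity;
3. **differential_positive** — keep residues with strictly more inhibitor
   than nucleotide contacts per frame (Δ > 0);
4. **sufficient_contact** — drop residues with very few inhibitor contacts
   overall (c̄_inh < 1 per frame);
5. **family_invariant** — drop residues whose alignment column varies across
   the kinase family: natural variation there shows the site does not
   control selectivity.

Survivors are ranked by Δ and each gets a suggested substitution — glycine by
default, which removes every side-chain van der Waals interaction at the
site.

Because real MD ensembles are large and slow to produce, the package also
ships a seeded synthetic-ensemble generator with planted per-residue contact
propensities (and the matching ground truth), plus a bundled worked-example
table for the 19 MERTK residues contacting MRX-2843.

## Worked example

Write the bundled MERTK/MRX-2843 worked-example fixture and run the triage in
fixture mode (from the transcribed per-residue table instead of raw
ensembles):

```sh
gatesite fixture --out fixture
gatesite triage --fixture-mode \
    --inhibitor fixture/mertk_worked_example.tsv \
    --critical  fixture/mertk_annotations.tsv \
    --msa       fixture/tam_family_synthetic.fasta \
    --msa-target MERTK \
    --numbering fixture/tam_family_numbering.tsv \
    --out report.json
```

which logs

```
INFO candidate A/LEU593 -> L593G (delta +3.20)
INFO candidate A/LEU671 -> L671G (delta +1.10)
INFO report written: report.json
```

The JSON report records the filter chain: 19 proximal residues → 8 after the
structural stage (Lys619 and Asp741 are annotated critical; nine residues
contact the inhibitor through their backbone) → 5 with more inhibitor than
ADP contacts → 3 promising sites (Leu593, Ile650, Leu671; Glu637 and Val669
have too few contacts overall) → 2 after the family stage, because the Ile650
column varies across the TAM family (Ala in TYRO3, Met in AXL). The final
candidates are **L593G** (Δ = +3.2 contacts/frame, top-ranked) and **L671G**
(Δ = +1.1).

The same pipeline runs on real ensembles:

```sh
gatesite synth --seed 1 --out data          # or your own multi-model PDBs
gatesite triage \
    --inhibitor data/inhibitor.pdb --ligand-resname MRX \
    --natural   data/natural.pdb   --natural-resname ADP \
    --critical  data/annotations.tsv \
    --out report.json
```

and as a library: `read_ensemble`, `residue_contact_profile`,
`differential_profile`, `run_triage`.

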
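# Methods

## Contact model

A close contact is a ligand-atom/protein-atom pair with Euclidean distance
strictly below a cutoff, 4.5 Å by default. The boundary is exclusive: a pair
at exactly 4.5 Å does not count. Contacts are enumerated per frame and summed
over the ensemble, so the counting unit is the atom-pair-per-frame — a pair
persisting through k frames contributes k. No distance weighting, interaction
typing (hydrogen bonds, π-stacking) or energy model is applied; the metric is
a pure count, which makes it robust and directly comparable between ligands.

All atoms present in the input participate by default, hydrogens included
(MD frames normally carry them); `heavy_only` drops H/D atoms either at parse
time or at counting time. Dropping hydrogens can only remove pairs, never add
them.

Cross-ensemble comparison uses per-frame means, which makes profiles from
ensembles of unequal length commensurable. The differential contact of a
residue is Δ = c̄_inhibitor − c̄_natural; "more contacts with the inhibitor"
means strict inequality of the means (a tie is not "more").

Backbone atoms are N, CA, C, O, the terminal OXT, and hydrogens attached to
them (amide H, terminal H1–H3, HA; for glycine also HA2/HA3). Everything else
on a protein residue is side chain; unknown atom names default to side chain.
A residue's backbone-mediation score is the backbone fraction of its
inhibitor contacts.

## Ensemble input

Ensembles are read from multi-model PDB files or directories of single-model
PDB files (lexicographic file order defines frame order, for determinism).
Alternate locations are resolved to the highest-occupancy copy, ties to
altloc A. Residue identity is (chain, author number, insertion code, residue
name) throughout. Frames are assumed imaged and whole: there is no
periodic-boundary handling, which is a documented limitation — feed
post-processed MD frames, not raw wrapped coordinates.

## Triage stages and thresholds

| stage | rule | default |
|---|---|---|
| proximal | frame occupancy ≥ `min_occupancy` | 0.05 |
| structural_ok | drop critical residues; drop backbone fraction ≥ `backbone_fraction_threshold` | 0.75 |
| differential_positive | c̄_inh > c̄_nat (strict) | — |
| sufficient_contact | c̄_inh ≥ `min_mean_contacts` | 1.0 /frame |
| family_invariant | alignment column identical across all homologs | — |

Each stage is a subset of the previous one. Design choices where the
procedure was genuinely open:

- **Proximity** is an occupancy criterion rather than a raw-count one: 5 % of
  frames is low enough to recover any persistently contacting residue and
  high enough to reject single-frame noise. It is configurable.
- **Backbone mediation** uses a 0.75 fraction threshold; in fixture mode
  (below) explicit per-residue flags take precedence, so a transcribed table
  reproduces a published selection exactly even though the underlying
  per-atom counts are unavailable.
- **Critical residues** (e.g. the catalytic lysine and the DFG aspartate of a
  kinase) are user-supplied annotations, not inferred — identifying them
  requires domain knowledge the contact statistics do not contain.
- **Conservation** is maximally strict: any difference at the column,
  including a gap, excludes the site. The rationale is that a site where the
  family already varies is a natural "mutation" that evidently does not
  separate inhibitor from nucleotide binding.
- Candidates are ranked by Δ descending (ties by residue number ascending)
  and annotated with a substitution to glycine by default: glycine removes
  every side-chain interaction, the most aggressive way to switch off the
  inhibitor's favorable van der Waals contacts. A candidate that already is
  glycine is flagged "no side chain to remove". Substitutions are suggestions
  only; the package never mutates coordinates and does not predict whether a
  mutant retains catalytic activity — that is wet-lab territory.

The fixture-mode input is a per-residue TSV (chain, resnum, icode, resname,
backbone_mediated, inhibitor_mean, natural_mean, low_contact). The bundled
worked example transcribes the 19-residue MERTK/MRX-2843 case; its membership
flags encode the published filter chain, while the numeric per-frame means
are synthetic values chosen to be consistent with every qualitative statement
(which residues prefer the inhibitor, which have very few contacts, and the
final ranking), since per-residue counts were never published. The bundled
TAM-family alignment is likewise synthetic: an ungapped three-sequence
fragment (MERTK numbering 585–745, TYRO3 from 516, AXL from 534) encoding
only the published positional correspondence — the Ile650 column reads
Ile/Ala/Met and the Leu593/Leu671 columns are invariant — not a claim about
the true full-length alignment.

## Synthetic ensemble generator

The generator emulates what matters to the pipeline — per-residue contact
statistics — not physics. Residues sit on a ring (radius 20 Å by default)
around a single-atom ligand at the origin; each residue carries four backbone
pseudo-atoms (N, CA, C, O) and two side-chain pseudo-atoms (CB, CG) with
legal PDB names so backbone classification is exercised realistically. Per
frame, a residue with contact propensity p places ⌊p⌋ + Bernoulli(p − ⌊p⌋)
of its designated atoms (side-chain, or backbone for backbone-routed
residues) at 3.0 Å from the ligand, so the expected mean contacts/frame
equals p exactly; all coordinates then receive Gaussian jitter (0.1 Å SD by
default — two orders of magnitude below the 1.5 Å margin to the cutoff, so
planted contacts essentially never flip). Contact events are independent
across frames; real MD frames are autocorrelated, so passing tests here says
nothing about effective sample sizes in real trajectories. A single RNG
stream per call makes identical configs byte-identical.

Default conditions are 50 residues × 200 frames. One residue is the planted
gatekeeper (inhibitor propensity 1.5, natural 0.25, side-chain routed, not
critical). The decoys are a fixed mixture of the failure modes each triage
stage must reject: silent residues (30 %), natural-ligand-preferring (20 %),
exact ties (15 %), backbone-routed inhibitor binders (15 %), low-contact
inhibitor-preferring (10 %), critical residues with strong inhibitor
preference (5 %), and modest inhibitor-preferring survivors whose expected Δ
(≤ 0.6) stays below the gatekeeper's (1.25) (5 %). At 200 frames the standard
error of an estimated Δ is ≈ 0.05, far below the 0.65 margin, so the
gatekeeper recovery tests have honest headroom rather than knife-edge
statistics. With integer propensities and zero jitter the generator is fully
deterministic (the noise-free limit).

## Numerical and degenerate-input choices

- Contact enumeration uses a dense distance matrix for up to 250 k candidate
  pairs per frame and a KD-tree beyond that; both paths apply the strict
  `<` cutoff and return pairs sorted by (ligand index, protein index). Tests
  pin both paths to an exhaustive double loop.
- A residue with zero contacts is omitted from profiles; in the differential
  table a residue missing on one side contributes a zero mean there. The
  inhibitor backbone fraction of a residue with zero inhibitor contacts is
  defined as 0.
- An empty ligand or protein partition is an error, as is an alignment-column
  lookup outside the target's numbering (the error names the residue).
  Annotations that match no proximal residue are logged and ignored.
- Reports are JSON with sorted keys and no timestamps; identical inputs and
  configuration give byte-identical reports.

## Problem sizes in the checks

The bundled acceptance script runs the worked-example triage (19 residues),
100 seeded default-noise recovery runs plus 20 noise-free runs of the
50-residue/200-frame generator, and 50 random frames (≤ ~500 atoms) against
the double-loop contact oracle; the whole script finishes in well under a
minute on one CPU.

## Known limitations

- No periodic-boundary imaging; no mmCIF or compressed trajectory formats in
  the core reader.
- The contact metric ignores interaction chemistry and strength; two 4.4 Å
  carbon pairs count the same as two hydrogen bonds.
- The conservation filter needs a trustworthy alignment and correct
  numbering offsets; it is only as good as its inputs.
- The package nominates sites; it cannot guarantee the suggested mutant is
  inhibitor-resistant or catalytically active.
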
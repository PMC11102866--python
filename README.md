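# nucseen

Quantitative analysis toolkit for pioneer-factor/nucleosome engagement
experiments: tiled-motif enrichment scoring, in vitro MNase dyad-density
mapping with superhelical-location (SHL) arithmetic, single-molecule FRET
dwell-time kinetics, and structural geometry (superposition, per-residue
RMSD, steric clashes, minor-groove anchors, DNA unwrap angles).  Every
pipeline input can also be produced by seeded synthetic generators with
ground-truth sidecars, so the full analysis chain is testable end to end.

## Modules

| module            | what it does |
|-------------------|--------------|
| `io_formats`      | FASTA, PDB/mmCIF, TSV count/fragment tables, CSV traces — strict validation, lossless round trips |
| `seen_seq`        | 1-bp tiled motif libraries on a positioning backbone; spike-in-normalized log2 bound/unbound enrichment profiles |
| `nuc_geometry`    | dyad distances, SHL labels (half-turn resolution), SHL relocation between nucleosome registers |
| `dyad_map`        | fragment length filtering (145–147 bp default), midpoint dyads, percent dyad density, log2 fold change, greedy position calling |
| `smfret_kinetics` | change-point bleach detection, trace QC, corrected FRET efficiency, 0.48-threshold two-state segmentation, exponential lifetime fits (including an exact sampling-bias-corrected two-state inversion), replicate t-tests |
| `struct_geom`     | Kabsch superposition, per-residue Cα RMSD, vdW clash detection, DNA-frame DBD docking, minor-groove anchor contacts, unwrap angles |
| `synthetic_data`  | deterministic generators for counts, fragments, FRET traces and coordinate sets, each with a truth sidecar |

Coordinates are 0-based half-open internally; all user-facing positions
(CLI, output tables) are 1-based.

## CLI

```sh
nucseen seen tile  --backbone 601.fa --motif TCAAGGCCA --step 1 -o library.fa
nucseen seen score --counts counts.tsv --spike-id widom601 -o profile.tsv
nucseen geom shl   --motif-start 128 --core 147 --dyad 74
nucseen dyad       --fragments frags.tsv --ref-length 180 -o density.tsv
nucseen fret       --traces traces.csv --alpha 0.05 --gamma 1.0 --threshold 0.48 -o fits.tsv
nucseen struct rmsd  --model-a free.pdb --model-b bound.pdb -o rmsd.tsv
nucseen struct clash --factor dbd.pdb --target nucleosome.pdb -o clashes.tsv
nucseen simulate seen|fragments|fret ... -o out
```

## Notes on dwell-time fitting

At frame intervals comparable to the state lifetimes, the plain mean of
threshold-segmented dwells is biased: each run overestimates its sojourn
by about half a frame, and opposite-state excursions shorter than the
frame interval are missed entirely, merging adjacent dwells.  The default
`markov` fitting method inverts both effects in closed form (the sampled
state sequence of an alternating two-exponential process is a two-state
Markov chain); the uncorrected and midpoint-corrected plain means remain
available via `--method naive|midpoint`.
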
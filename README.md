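# rnapcollide

Quantitative analysis of transcriptional collisions in bacteria.

When an elongating RNA polymerase (RNAP) runs into a DNA-bound obstacle —
a tightly bound protein roadblock, or a second RNAP transcribing head-on —
it backtracks and rotates its *swivel module* (the clamp-containing
sub-assembly: β 1241–1341 plus four β′ segments) relative to its
structural core, entering a long-lived paused state. `rnapcollide`
implements the measurements that characterise this response, for
structural biologists and biochemists working on transcription:

- **Swivel angle** — two-stage Cα superposition: align the structural
  cores of query and reference elongation complex (EC), then extract the
  axis–angle of the residual rotation mapping the reference swivel module
  onto the query's. The active EC defines 0°; collided and paused
  complexes score 2–6°.
- **Downstream-DNA deformation** — PCA frame over the centers of mass of
  twelve downstream nucleotides of the reference EC; query displacement
  is projected onto PC1/PC2 and averaged, giving the signed deformation
  that couples linearly to swiveling.
- **Steric collision scanning** — walk a structure base-by-base along the
  DNA helical axis (screw transform from backbone superposition) and
  score clash with a fixed obstacle by solvent-excluded-surface (SES)
  overlap volume, `V(A) + V(B) − V(A∪B)`, on a sub-voxel-accurate grid.
- **Roadblock efficiency (E_RB)** — gel-lane quantification
  `(roadblock − bg)/(scaffold − bg)`, anchored to 1 at low salt and
  renormalised across conditions; complex-stability time courses fitted
  with a bi-exponential `a₁e^(−k₁t) + a₂e^(−k₂t)` and half-life CI by
  parametric bootstrap.
- **SEnd-seq classification** — paired 5′/3′ RNA reads assigned to the
  forward or reverse transcription unit by summed Smith–Waterman scores
  (affine gaps: +2/−1/−5/−0.5), with end-separation (>15 nt) and
  start-site-window filters, transcript-length profiles and a
  hairpin-boundary drop statistic.
- **Statistics** — Welch t-tests with Benjamini–Hochberg correction.
- **Synthetic generators** — mock two-module polymerases with known
  swivel rotations, ideal B-DNA (3.4 Å rise, 10.5 bp/turn), collision
  scenes, read sets, decay curves and titration tables, all
  seed-reproducible with built-in ground truth.

## Worked example

```python
from rnapcollide import compute_swivel
from rnapcollide.synthetic import MockPolymeraseSpec, make_mock_polymerase

reference, query = make_mock_polymerase(
    MockPolymeraseSpec(seed=1, swivel_angle=2.8, coordinate_noise=0.05)
)
result = compute_swivel(query, reference)
print(f"swivel angle : {result.angle:.3f} degrees")
print(f"core fit     : {result.core_rmsd:.3f} A rmsd over {result.n_core_pairs} CA pairs")
```

prints

```
swivel angle : 2.800 degrees
core fit     : 0.087 A rmsd over 1386 CA pairs
```

The mock polymerase was built with its swivel module rotated by exactly
2.8° about a known axis (the magnitude seen in roadblock-collided
complexes) plus 0.05 Å coordinate noise; the measurement recovers it from
the 1386 shared core and 880 swivel Cα pairs. Real structures work the
same way: `read_structure("6rh3.cif")` for the reference EC,
`infer_rnap_chain_map` to resolve chain labels, then `compute_swivel`.

More end-to-end walkthroughs live in `examples/` (one script per
capability: swivel angle, DNA displacement, collision scan, roadblock
efficiency, complex stability, SEnd-seq pipeline); each prints the
numbers it computes and one line on what they mean. A thin CLI mirrors
the library for shell use: `rnapcollide swivel --query q.pdb --reference
ref.pdb`, `rnapcollide collide-scan ...`, `rnapcollide simulate ...`;
see `rnapcollide --help`.

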
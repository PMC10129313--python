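# Methods

## Overview

`abframes` predicts the backbone structure of antibody variable fragments
(paired VH/VL or single-domain nanobodies) directly from sequence
embeddings, estimates its own per-residue error, and idealizes the
resulting backbone by gradient descent. The pipeline is:

1. **Embedding front end.** A language-model embedder supplies, per chain,
   an L×512 final hidden state and an L×L×64 stack of attention maps
   (8 layers × 8 heads). Affine projections reduce these to node features
   h_i (L×d_node) and edge features e_ij (L×L×d_edge). Paired chains are
   concatenated with inter-chain edges initialized to zero and no
   chain-break token (positional information is per-chain in the
   embedder). The embedder is an interface: the package ships a
   deterministic synthetic embedder with the same output shapes (one-hot
   residue codes plus smoothed positional features; row-normalized,
   distance-decaying attention maps), and any embedder producing the same
   container can be plugged in.
2. **Encoder.** Four blocks, each a graph-transformer node update followed
   by outgoing and incoming triangular multiplicative edge updates. The
   node attention uses per-head query/key/value maps plus a learned
   projection of the incident edge added to the key and to the message;
   attention weights are exponentials of the scaled dot product,
   normalized over source positions; a gated residual
   (β = σ(W_g[ĥ; h; ĥ−h])) mixes the update with the previous embedding,
   followed by a width-256 feed-forward transition. Edge updates form
   gated "left"/"right" transforms a_ij, b_ij (width 2·d_edge) and
   accumulate Σ_k a_ik⊙b_jk (outgoing) or Σ_k a_ki⊙b_kj (incoming), with
   separate parameters per direction.
3. **Template incorporation.** Two fixed-frame invariant-point-attention
   (IPA) layers over frames fitted from template coordinates. Attention
   is restricted to residue pairs that *both* carry template coordinates;
   untemplated residues receive only the feed-forward transition, so an
   absent template reduces exactly to the transitions-only path.
4. **Structure module.** Three IPA layers with *separate* weights, each
   emitting a per-residue rigid update (unit-quaternion rotation +
   translation) composed onto frames initialized at the identity with Cα
   at the origin. Gradients propagate through the rotation composition.
   Translations are predicted in units of 10 Å so the update weights stay
   O(1) while the fold traverses tens of Å. Final coordinates place the
   four frame atoms (N, Cα, C, Cβ — glycine gets a virtual Cβ) at ideal
   geometry in each frame.
5. **Error head.** Two fixed-frame IPA layers over the *final predicted*
   structure's frames, fed by a fresh affine projection of the initial
   language-model features (not the encoder output), ending in a softplus
   map to non-negative deviations for all four frame atoms; the Cα
   channel is trained and reported. The predicted frames enter the graph
   as constants, so the error objective sends exactly zero gradient into
   the structure-prediction weights.

With default hyperparameters (d_node = d_edge = 64; 8 GT heads of width
32, feed-forward 256; template/structure IPA with 8 heads, scalar width
16, 4 query points; error IPA with 4 heads) the network has 1,645,946
trainable parameters. IPA value points per head default to 8, inheriting
the cited attention algorithm's 4-query/8-value split; the table-driven
"point dimension" sets the query side.

## Frames and geometry

A residue frame has Cα at the origin, x-axis along Cα→C, and N in the
xy-plane (Gram–Schmidt fit from N/Cα/C). Ideal bond lengths and planar
angles are standard restraint-library values and ship as an editable
config block (`IdealGeometry`): N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å,
Cα–Cβ 1.521 Å, C–O 1.231 Å; N–Cα–C 111.2°, Cα–C–N 116.2°, C–N–Cα 121.7°,
N–Cα–Cβ 110.4°, C–Cα–Cβ 110.1°, Cα–C–O 120.8°; ω trans (180°). Angles are
radians internally, degrees at interfaces; all coordinates are Å.

Carbonyl oxygens are not predicted; when a metric or output format needs
them they are placed geometrically in the peptide plane (opposite the
bisector of the Cα–C and N(next)–C directions; chain-terminal O placed in
the N/Cα/C plane at the ideal Cα–C–O angle).

## Training objective

Per example, the loss is a sum of three terms:

* **Coordinate loss** — mean squared deviation (Å², per atom) of the four
  frame atoms after optimal (Kabsch) superposition of the label onto the
  prediction. The optimal transform is computed from the current numeric
  coordinates and held constant in the graph; by the envelope theorem the
  gradient through it is exact.
* **Bond-geometry loss** — mean L1 deviation of backbone inter-atomic
  distances one and two positions apart along the N→Cα→C mainchain (plus
  Cβ to its bonded Cα and flanking N/C), from values fixed by ideal
  covalent geometry, scaled ×10 and clamped at 1. Because every reference
  distance is torsion-independent, an ideally built structure scores
  exactly zero regardless of its φ/ψ angles. The clamp means early
  training (geometry far from ideal) receives no bond-geometry gradient,
  letting the model learn the global arrangement first.
* **Error-prediction loss** — L1 between the predicted Cα deviation and
  the realized one, the latter measured after Kabsch alignment on the
  beta-annotated (immunoglobulin-strand) residues, mirroring how antibody
  models are conventionally scored.

Training steps sample one structure (batch size 1): a source is drawn
under inverse-size example weighting (each source's total probability is
uniform — with the three structure sources of sizes 4275 / 16,141 /
22,132 each receives ~one third of draws), an example is drawn from it,
and with probability 0.5 the native structure is corrupted into a partial
template: 1–6 segments of 20 consecutive residues (starts uniform, overlap
allowed, so 20–120 residues total) are hidden from the template attention;
otherwise no template is given. The optimizer is RAdam at initial learning
rate 5e-4 with cosine-annealed decay, plus global gradient-norm clipping
(cap 1.0, configurable) — a standard stabilizer for the noisy batch-size-1
regime. Full-scale settings (2×10⁶ steps) are retained as documented
presets; desk-scale runs use the toy preset below.

Ensembles of independently seeded models are resolved per target by the
90th-percentile per-residue predicted error (linear interpolation between
order statistics; ties to the lowest index) — a rule that keys on the
worst-predicted region, typically CDR3, rather than the mean.

## Refinement

Predicted backbones are idealized under a four-term objective: squared
deviations of bond lengths (Å), planar angles and the ω dihedral
(radians, angle-wrapped) from ideal values, each *summed* over
occurrences, plus the training-form coordinate restraint (mean squared Å²
after Kabsch) anchoring the refined structure to the input prediction.
Summing the idealization terms keeps a single distorted bond from being
diluted by chain length: with per-term means a +0.3 Å bond stretch
settles ~0.13 Å from ideal, while the sum form restores it to within
0.002 Å in the same budget.

Optimization runs Adam on the raw coordinates, 80 steps at learning rate
0.02, with two safeguards:

* **Monotone acceptance.** A step that would increase the objective is
  rejected; the adaptive moments are reset and the step size backed off
  (×0.5, floor lr/256, recovering ×1.1 on acceptance). Plain Adam is not
  monotone — from an exact minimum its normalized steps amplify ~1e-12
  noise gradients into visible drift — whereas the safeguarded trace is
  non-increasing by construction and an already-ideal input moves < 1e-7 Å.
* **Canonical pose.** Optimization happens in a deterministic canonical
  frame (centroid at origin, principal axes, skewness-fixed signs) and is
  mapped back afterwards, making refinement commute exactly with rigid
  motions of the input; element-wise Adam is otherwise not rotation
  equivariant.

Relative term weights are exposed in config and default to parity.
Full-atom force-field refinement and side-chain packing are deliberately
out of scope (external post-process).

## Evaluation metrics

* **Regions** follow Chothia CDR windows (H1 26–32, H2 52–56, H3 95–102;
  L1 24–34, L2 50–56, L3 89–97). Numbering itself is delegated: fixtures
  carry region labels, and real chains accept an externally computed
  numbering table; insertion codes are stripped.
* **Region RMSD** is backbone heavy-atom (N, Cα, C, O) RMSD after one
  Kabsch fit on the chain's framework atoms; CDR RMSDs reuse that
  transform without re-alignment, so loop displacement relative to the
  framework is counted. Missing O atoms are placed geometrically.
* **OCD** sums over four inter-chain coordinates — packing angle (torsion
  between the two domains' principal Cα axes about the centroid
  connection), inter-domain distance, and the two opening angles (each
  axis against the connection) — the absolute deviation from the second
  structure, each divided by a population standard deviation. Residue
  sets default to framework Cα atoms and the σ values (2.6°, 0.4 Å, 1.9°,
  1.6°) are configuration, not code: the defining convention lives in
  prior literature and users can substitute their own sets/σ. An OCD of 4
  therefore means roughly one σ of deviation per coordinate.
* **Calibration** is Spearman rank correlation (average ranks on ties)
  with the two-sided t-approximation p-value.
* **Benchmark filter**: deposition-date window, resolution cutoff
  (default keeps ≤ 3.0 Å; the inverted rule is selectable), CDR-H3 length
  cap (20 by Chothia), then greedy single-linkage clustering at 99%
  global-alignment sequence identity keeping the first representative.

## Synthetic data

Toy Fv structures are grown residue-by-residue at exactly ideal covalent
geometry from per-residue φ/ψ plans: framework residues use extended
strand angles (−120°, +120°) and carry beta flags; CDR segments sample a
permissive turn basin (φ ∈ [−90°, −50°], ψ ∈ [−60°, −10°]) and carry
region labels. Two chains (default 32 + 28 residues, three CDRs each) are
placed with a rigid flip-and-offset to form a pseudo-interface; a clash
check (non-neighbour atoms > 2 Å) retries with re-seeded loop angles.
Sequences cycle a fixed framework pattern with seeded random CDR letters.
Gaussian coordinate noise (σ per axis) provides perturbed variants for
error-label and metric tests.

These toys reproduce the *contracts* of antibody data — paired chains
with contiguous CDR loops, strand-annotated frameworks, ideal local
geometry, embedder-compatible sequences — but not its physics: no real
immunoglobulin fold, no side chains, no packing constraints, and CDR
conformations unrelated to canonical classes. Tests passing on them
demonstrate that the architecture, losses, and metrics behave as
specified, not that the network predicts real antibody structures; that
would require training on experimental data with a pre-trained embedder.

## Desk-scale preset and problem sizes

`ModelConfig.toy()` is a 2-layer-scale preset (2 GT blocks; 1 template,
2 structure, 1 error IPA layers; d_node 32, d_edge 8, 2 heads, 2 value
points) used by `train-toy` and the test suite. The training-recovery
check overfits 3 paired toy fixtures (60 residues each) for 2000 steps at
the defaults above (template corruption active), reaching ~0.45 Å Cα RMSD
to each training target on a single CPU in about four minutes. The
stochastic-rate checks use 10,000 corruption draws on a 200-residue toy
and 30,000 source draws.

## Numerical choices

The network and both gradient-based procedures run on a small
reverse-mode automatic-differentiation engine over float64 NumPy arrays
(single-threaded deterministic; fused layer-norm and softmax with
analytic backwards; contraction-style einsum). Attention softmaxes
subtract the row maximum inside the exponential — mathematically the
identity, numerically overflow-proof. Rotation updates are normalized
quaternions (1, b)/‖·‖, guaranteeing proper orthonormal matrices and
smooth gradients at the identity. Kabsch superposition uses SVD with the
determinant sign correction; degenerate (collinear, < 3 point) inputs are
rejected. Checkpoints are `.npz` archives of all parameters plus the
JSON-encoded configuration and a content hash checked on load.

## Known limitations

* The synthetic embedder carries no evolutionary or structural knowledge;
  predictions from it are only meaningful after (over)fitting.
* Only the four frame atoms (plus placed O) are modelled — no side
  chains, no hydrogens.
* OCD σ values and residue sets are nominal defaults, not fitted to an
  experimental ensemble.
* The built-in region assignment requires fixture metadata or an external
  numbering table; it does not re-implement an antibody numbering tool.
* Refinement enforces local ideality only; it cannot repair topological
  errors (e.g. a mis-folded loop threading the other chain).
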
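# polclust

Analysis toolkit for RNA Polymerase II (RNAPII) clustering and molecular
kinetics during zygotic genome activation (ZGA) in early *Drosophila*
embryos. It is aimed at researchers quantifying live-embryo single-molecule
tracking (SMT) and volumetric light-sheet imaging of transcription: it
infers diffusion-state occupancies and chromatin-bound fractions from
trajectory tables, decomposes the bound fraction into non-specific /
initiating / elongating components via drug-perturbation arithmetic,
measures displacement-angle anisotropy, detects RNAPII clusters both from
trajectory density and from 3D movies (with histone-locus-body removal and
lifetime mixture modeling), analyzes MS2/MCP transcription-burst traces, and
simulates polymerase loading at a bursting gene to ask when a cluster is
visible over nuclear background.

## The models at the core

**Diffusion-state inference.** Each trajectory moves with a single diffusion
coefficient `D` drawn from a mixture over a fixed log-spaced grid of 100
values in [10⁻³, 10²] µm²/s. The per-axis jump vector of a trajectory with
localization error σ is Gaussian with tridiagonal covariance
(`2DΔt + 2σ²` on the diagonal, `−σ²` off it — consecutive jumps share the
middle localization's noise), which diagonalizes in a sine basis, so the
exact likelihood costs one DST per trajectory. Grid occupancies are fit by
EM; each trajectory gets `D = exp(Σᵢ wᵢ ln Dᵢ)` from its posterior weights,
and bound / intermediate / fast states are delimited by occupancy minima.

**Bound-fraction decomposition.** With `b_TRI`, `b_AMA`, `b_VEH` the bound
fractions under initiation block (triptolide), elongation block
(α-amanitin), and vehicle:

    nonspecific = b_TRI,  initiating = b_AMA − b_TRI,  elongating = b_VEH − b_AMA

with quadrature error propagation and relative-error propagation for fold
changes.

**Anisotropy.** `f = P(θ ∈ [150°, 180°]) / P(θ ∈ [0°, 30°])` over turning
angles between consecutive jumps ≥ 0.2 µm of non-bound trajectories; `f = 1`
for free diffusion, `f > 1` under confinement.

**Cluster imaging and lifetimes.** Nuclei are normalized to mean intensity,
clusters segmented by a morphological reconstruction chain plus watershed,
filtered at mean enrichment ≥ 1.65, tracked with a 600 nm z-gate, and
lifetime distributions summarized by a two-component Gaussian mixture
(short- vs long-lived clusters).

**Loading simulator.** While a promoter is ON (duration `t_on`), one
polymerase loads per 0.1 s step with probability `k_on`, elongates at
2.5 kb/min over a 2.8 kb gene, and may dissociate with probability `k_off`;
~50,000 nuclear RNAPII molecules (scaled to a 3-slice central slab of the
5 µm nucleus) form the background, every molecule rendered as a 400 nm FWHM
Gaussian. With `k_off = 0` the steady-state engaged count obeys Little's
law, `L = (k_on/Δt) · (gene length / elongation rate)`.

## Worked example

```python
import polclust as pc

# simulate an SMT experiment with known state fractions, then recover them
cfg = pc.SmtSimConfig(n_trajectories=10_000,
                      state_fractions=(0.37, 0.33, 0.30),
                      state_diffusion_coefficients=(0.002, 0.2, 8.0),
                      localization_sigma=0.03, seed=1)
table, truth = pc.generate_smt_trajectories(cfg)
profile = pc.estimate_occupancy(table, sigma_loc=0.03, frame_interval=0.01)
bins = pc.find_state_boundaries(profile)
d = pc.assign_trajectory_D(profile.responsibilities.to_numpy(), profile.grid)
fr = pc.compute_fractions(d, profile.responsibilities.index % 10, bins)
print(bins.boundaries)   # (0.029150530628251757, 1.072267222010323)
print(fr.mean.round(3))  # [0.395 0.303 0.302]
```

The two boundaries (≈0.03 and ≈1.1 µm²/s) split the occupancy profile into
bound / intermediate / fast states; the recovered fractions land within a
few points of the generating mixture (0.37/0.33/0.30), the bound state
slightly inflated by short-trajectory misclassification. Decomposition of
measured bound fractions works directly on summary values:

```python
r = pc.fold_change((0.51, 0.08), (0.37, 0.05))
print(round(r.value, 1), round(r.sd, 1))  # 1.4 0.3
```

A command-line interface mirrors the library
(`polclust simulate|fit-kinetics|decompose|anisotropy|cluster-traj|segment-clusters|bursts|simulate-polii|run`).

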
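# lidtraj

Trajectory analysis of two-domain proteins with mobile lids: domain-additive
mass-weighted mean square deviation (MSD), spatiotemporal nearest-contact
tracing, and geometric-mean proximity / interconnectivity networks.

## The problem

Hsp70 chaperones such as *E. coli* DnaK bind substrate peptides in the
substrate-binding domain (SBD), a rigid β-sandwich core (residues 389–507)
capped by a five-helix "lid" (residues 508–607).  Simulations of the
SBD–peptide complex show the lid is not a rigid block: its terminal helices
reorient until a lid residue (Ser595 in the wild-type complex) forms a
persistent contact with the charged N-terminus of the bound hepta-peptide
NRLLLTG.  Quantifying that behaviour needs four statistics, which this
package implements for anyone analysing trajectories of proteins with a
rigid core and a mobile sub-domain:

1. **Domain-additive MSD** (module `lidtraj.msd`).  For atoms with masses
   $m_i$ and positions $r_i(t)$,

   $$\mathrm{MSD}_\text{whole}(t_1,t_2)
     = \frac{\sum_i m_i \lVert r_i(t_1)-r_i(t_2)\rVert^2}{M_\text{whole}},
   \qquad
   \mathrm{MSD}_\text{domain}
     = \frac{\sum_{i\in \text{domain}} m_i \lVert \Delta r_i\rVert^2}{M_\text{whole}},$$

   so per-domain contributions sum *exactly* to the whole:
   $\mathrm{MSD}_\text{whole} = \sum_d \mathrm{MSD}_d$.  The decomposition
   answers "which domain moved" with well-defined fractional contributions.

2. **Nearest-contact tracing** (`lidtraj.contacts`).  Per frame, the lid
   residue with the smallest minimal heavy-atom distance to the peptide,
   binned into close (< 3 Å), mid (3–6 Å) and far (≥ 6 Å); a persistence
   criterion turns the binned trace into a contact-formation time.

3. **Proximity factor and strength** (`lidtraj.proximity`).  Over a window
   of $n$ frames the proximity factor of residues $i,j$ is the geometric
   mean of the per-frame minimal distance,
   $P_{ij} = \left(\prod_t d_{ij}(t)\right)^{1/n}$ (computed in log space),
   and the interaction strength is $S_{ij} = 1/P_{ij}$.  The geometric mean
   rewards pairs that stay close with small fluctuations.

4. **Interconnectivity networks** (`lidtraj.proximity`).  Residue pairs
   with $P_{ij}$ at or below a cutoff (4 Å display, 3.5 Å reporting) form
   a network; intersecting networks across conditions yields the contacts
   that hold the lid together in (almost) every condition.

A first-class synthetic-trajectory generator (`lidtraj.synthetic`) emulates
the system these analyses assume — rigid core, mobile lid arm starting
22 Å from the peptide, a scheduled rapid approach closing to 2.3 Å,
Gaussian noise — with analytic ground truth, so every estimator is tested
by parameter recovery.  See `docs/methods.md` for the model and its
limitations.

## Worked example

```sh
$ lidtraj simulate --preset approach --seed 1 --outdir run
wrote run/approach.pdb (250 frames)
$ lidtraj contacts run/toy_complex.pdb run/approach.pdb \
      --regions run/regions.yaml --out trace.tsv
wrote trace.tsv; formation time: 1490 ps
$ lidtraj proximity run/toy_complex.pdb run/approach.pdb \
      --regions run/regions.yaml --window last:0.2 --out prox.tsv
wrote prox.tsv (45 pairs, window 2000-2490 ps)
```

The approach preset programs a lid-to-peptide contact that completes at
1494 ps; the persistence-based estimator reports 1490 ps — the first
sampled frame of the stable close contact, within one 10 ps sampling
interval of the programmed event.  The head and tail of `trace.tsv` show
the lid tip (residue 10 of the lid chain) starting 22 Å from the peptide
and ending in a stable close contact fluctuating around 2.3 Å:

```
frame  time_ps  nearest_residue  distance_A  bin
0      0.0      10               21.9999     far
1      10.0     10               21.8227     far
...
248    2480.0   10               2.8739      close
249    2490.0   10               2.3464      close
```

The same analyses run on real data: `lidtraj msd structure.pdb traj.pdb
--domains beta,lid --fit beta`, `lidtraj network prox.tsv --cutoff 4.0`,
`lidtraj report edges.tsv` (which flags contacts shared with the packaged
published condition sets), or `lidtraj run --config run.yaml` for the full
pipeline with a provenance manifest.

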
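# gabatlas

Consistent whole-brain densities of inhibitory neuron types — GAD67+
(GABAergic), PV+, SST+ and VIP+ — for a voxelized, hierarchically annotated
brain volume, built from three heterogeneous evidence sources:

1. **literature measurements** (densities, absolute counts, percentages of
   neurons or cells, each with an uncertainty),
2. **marker-expression volumes** (filtered ISH slice stacks, binarized with
   Otsu's threshold and summarized per region), via fitted linear transfer
   functions from region mean intensity to density, and
3. **neuron-count constraints** from a Nissl-derived cell density stage.

It targets quantitative neuroanatomists and modellers who need per-region
counts that are simultaneously close to published values and globally
coherent: subtype sums cannot exceed the GABAergic total, no population can
exceed the region's neuron count, and every parent region must equal its
own voxels plus its children.

## Model

For every region *r* of the hierarchy **R**, neuron counts decompose as

    nNeu_r = nInh_r + nExc_r + nOther_r,      nInh_r = nGAD_r
    nGAD_r = nPV_r + nSST_r + nVIP_r + nRest_r

with PV/SST/VIP mutually exclusive and all GAD67-positive. Unconstrained
estimates η (with uncertainty σ) per (region, type) come from the average
of literature sources where published, from the transfer function
y = α·x (fit per marker and per group — cerebellum, isocortex, rest;
α = Σxy/Σx²) where only expression is available, and from child aggregation
otherwise. Designated purely-inhibitory regions (isocortex layer 1,
cerebellar molecular layer, thalamic reticular nucleus) take nGAD = nNeu.

The reconciliation step finds corrected counts x minimizing the
confidence-weighted correction

    min Σ_r |x_r − η_r| / σ_r
    s.t.  0 ≤ x_{r,t} ≤ nNeu_r
          0 ≤ x_{r,GAD} − (x_{r,PV} + x_{r,SST} + x_{r,VIP}) ≤ nNeu_r
          x_{parent,t} = x_{own,t} + Σ_children x_{c,t}

linearized with slack variables z ≥ |x − η| and solved exactly as an LP
(HiGHS), after a greedy feasibility pre-pass that caps estimates at neuron
counts and restores subtype coherence with the smallest interval fraction
q ∈ [0, 1]. Estimates corrected beyond η ± σ are flagged. Finally, cells
are placed voxel by voxel proportionally to the local cell density and
labeled by nested uniform selection (inhibitory ⊃ PV, SST, VIP; remainder
InhR; the rest ExcOther), each with a uniform position inside its voxel.

A synthetic-fixture module generates toy brains (nested-box annotation,
Nissl-like volume, per-marker slice stacks, noisy literature tables) with
ground truth that satisfies every constraint exactly, so the whole pipeline
is testable without any external data.

## Worked example

Generate a 13-region toy brain and run the pipeline:

```sh
$ gabatlas make-fixtures -o demo --seed 1
fixture bundle with 13 regions written to demo
$ gabatlas optimize -c demo/config.yaml
objective 9.5416; 15.4% of regions flagged
$ gabatlas fit -c demo/config.yaml
fitted 12 transfer functions -> demo/results/fit_report.csv
$ gabatlas place -c demo/config.yaml
placed 29751 cells -> demo/results/cells.csv
$ gabatlas validate -c demo/config.yaml --trials 8
hold-out within-interval fraction: 0.600
```

The `optimize` line reports the LP objective — the total correction applied
to the unconstrained estimates in units of their standard deviations — and
the fraction of regions whose corrected value left the η ± σ band (here 2
of 13). `fit_report.csv` holds one through-origin slope per marker and
group with its standard error and explained-sum R², e.g.

```
marker,group,alpha,std_alpha,r_squared,n_points
GAD67,cerebellum,651719.2556031042,32529.12193194496,0.83070182272314,3
GAD67,isocortex,365543.64600849565,56161.573398552704,0.88577861535107,2
```

(α in cells/mm³ per unit mean binarized intensity). `cells.csv` lists one
row per placed cell (x, y, z in μm, region id, label); the hold-out
fraction is the share of withheld literature values whose reconciled
density falls inside the withheld mean ± std.

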
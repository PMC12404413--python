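# latentwb

Latent-space whole-brain modelling of resting-state fMRI for disorders of
consciousness (DoC).

Resting-state BOLD recordings of DoC patients (unresponsive wakefulness
syndrome, UWS; minimally conscious state, MCS) and healthy controls (CNT)
carry diagnostic information in their functional connectivity, but
region-level whole-brain models are expensive to fit per patient and hard to
compare across scanners. `latentwb` works in a low-dimensional latent space
instead: parcellated BOLD series (regions x time, TR = 2 s) are reduced to
d ~ 15 latent dimensions by an auto-encoder or PCA, a stochastic whole-brain
model is calibrated to each subject there, and model-based biomarkers are
read off the fitted objects. It is intended for researchers fitting
personalized whole-brain models to clinical resting-state cohorts.

## The models and the fit

Two generative models run on the latent nodes (RK4, dt = 0.05 s, additive
noise, subsampled at TR):

* **Hopf** — Stuart–Landau oscillators near the bifurcation,
  x' = (a − x² − y²)x − ωy + Σⱼ C_ij(x_j − x_i) + ση, with per-node ω from
  the spectral edge frequency at 50% power (SEF50) of the data;
* **AHP** — a neuron–astrocyte mean field per node (voltage h, synaptic
  facilitation x, depression y) whose afterhyperpolarization phases switch
  the voltage equilibrium and timescale (T₀, τ₀) through a burst cycle:
  bursting/rest → medium AHP (depth T_h, rate 1/τ_mAHP) → slow AHP
  (rate 1/τ_sAHP); long-range input Σⱼ J_ij x_j y_j (h_j − T₀)⁺.

Calibration maximizes the structural similarity index
SSIM(A, B) = (2μ_Aμ_B + c₁)(2σ_AB + c₂) / ((μ_A² + μ_B² + c₁)(σ_A² + σ_B² + c₂))
between empirical and simulated latent FC (7x7 sliding window, L = 1),
alternating (i) a multiscale random search over the node parameters Θ
(N_max = (4 − iter)×1000 candidates, N_sim = 10·iter + 15 averaged
simulations each, ranges re-centred and halved around the best value) and
(ii) a pseudo-gradient descent on the coupling — the generative effective
connectivity (GEC):

    GEC_ij += ε [(FC_emp − FC_sim) + (FC_emp^τ − FC_sim^τ)]_ij,

with ε = 0.01 and a forward time shift τ = 3 × TR = 6 s, so the asymmetric
lead–lag structure shapes an asymmetric coupling. Biomarkers: signed-graph
measures of the GEC (clique bipartitions, inter-clique statistics,
sparsity, asymmetry, centrality/clustering, pairwise Kolmogorov–Smirnov
group tests), RSN decoding of latent dimensions, and UMAP + HDBSCAN
clustering of the fitted node parameters against CRS-R outcome categories.

Patient data are not redistributable, so the package ships a seeded
synthetic-cohort generator (two-clique couplings with condition-dependent
densities, model-simulated latent dynamics, 100-region surrogates, clinical
metadata) that every stage is tested against. See `docs/methods.md` for
assumptions, parameter tables and limitations.

## Worked example

Generate a small synthetic AHP cohort, fit one subject at desk scale and
extract its GEC graph measures:

```bash
$ latentwb generate --out cohort --n-per-group 2 --model ahp --duration 300 --seed 7
wrote 6 subjects to cohort

$ cp cohort/cnt000_bold.tsv cnt000_latent.tsv   # already latent-space series
$ latentwb fit --model ahp --latent cnt000_latent.tsv --out cnt000_fit.json \
      --scale small --seed 11
fit cnt000_latent: SSIM 0.777

$ latentwb graph --gec cnt000_fit_gec.tsv --out cnt000_graph.json
wrote graph measures to cnt000_graph.json
```

`cnt000_graph.json` then contains (abridged):

```
sparsity: 0.008889          # fraction of |GEC| entries below 0.015
asymmetry: 0.07628          # mean |GEC - GEC^T| / 2
mean_conn: 0.08037          # mean GEC entry
interclique_pos_mean: 0.3253   # mean positive boundary-edge weight
interclique_neg_mean: -0.3954  # mean negative boundary-edge weight
within_clique_pos_density: 0.5783
```

The fit SSIM of 0.777 is the combined (direct + time-shifted FC) score of
the final coupling at the reduced `--scale small` budget; full-schedule
fits use the budgets in `docs/methods.md`. The graph numbers are the
subject's GEC biomarkers: a near-dense coupling (sparsity ~0.9%), mild
asymmetry introduced by the shifted-FC term, and the two-clique structure
visible as positive within-clique boundary weights against negative
inter-clique ones.

Cohort-level comparisons and clustering follow the same pattern
(`latentwb graph-compare`, `latentwb cluster`); `latentwb reduce` maps
100-region recordings to the latent space and `latentwb simulate` runs
either model forward (optionally through the Balloon–Windkessel
hemodynamic stage).

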
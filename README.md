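# cdisim

Individual-based simulation of contact-dependent growth inhibition (CDI) in
radially expanding 2D bacterial colonies, with the analysis suite used to
quantify the outcome of spatial competition.

Cells are rigid capsules that elongate exponentially, divide at a stochastic
target length, and push each other apart under viscous drag — growth jams in
the colony interior and continues at the expanding edge. An inhibitor strain
intoxicates susceptible target cells on sustained contact: inhibition and
recovery are exact stochastic events scheduled with a next-reaction-method
(Gibson–Bruck) queue over the dynamic contact graph. The model's knobs are
the growth rate α, inhibition rate η (per hour per contacting inhibitor),
toxicity δ (fractional growth reduction of intoxicated targets), recovery
rate μ, and inhibitor cost β.

## Layout

- `src/cdisim/geometry.py` — capsule primitives, segment distance, grid-hash
  contact detection (`build_contacts` matches the all-pairs oracle exactly).
- `src/cdisim/mechanics.py` — growth, overlap-pressure attenuation, damped
  pairwise overlap relaxation, division.
- `src/cdisim/kinetics.py` — CDI state machine and the indexed priority
  queue scheduler (schedule / rescale / fire / sync with the contact graph).
- `src/cdisim/engine.py` — configuration, inoculation, main loop, TSV
  snapshot I/O, deterministic replay.
- `src/cdisim/analysis.py` — neighbor index, radial annulus profiles,
  sector counting and sizing via iterated circular Gaussian smoothing,
  relative fitness.
- `src/cdisim/cli.py` — `cdisim run | sweep | analyze | plot`.

## CLI

```sh
# one desk-scale run (50 um inoculum, 350 steps), analysis written alongside
cdisim run --profile desk --seed 1 --out-dir out/ --set eta=1.0 --set delta=0.2

# full-scale configuration of the source experiments (700 steps = 35 h)
cdisim run --profile full --seed 1 --out-dir out_full/

# parameter sweep with replicates (seeds = base seed + replicate index)
cdisim sweep --eta 0.1 --eta 1.0 --delta 0.2 --delta 1.0 \
    --density 160 --replicates 10 --out-dir sweep/ \
    --set inoculum_radius=20 --set n_steps=200

# re-analyze written snapshots; neighbor index needs both endpoints
cdisim analyze out/snapshot_final.tsv out/snapshot_t0.tsv --out-dir analysis/
cdisim plot out/snapshot_final.tsv --out-dir plots/
```

Configuration can also come from a flat TOML file (`-c sim.toml`); every key
of `SimulationParams` is optional and CLI `--set key=value` overrides win.
Snapshots are plain TSV tables (one row per cell) with a `#`-prefixed header
carrying the params hash and seed, so any run can be replayed or analyzed
externally.

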
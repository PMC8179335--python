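# fieldunfold

Analysis pipeline for **electric-field-induced unfolding of gas-phase
proteins**, and for how that unfolding would register in time-resolved X-ray
experiments — single-particle imaging (SPI) at free-electron lasers and
gas-phase SAXS.

Strong static fields (10⁴–10⁵ kV cm⁻¹ scale) unfold an oriented gas-phase
protein along well-defined pathways.  Given ensembles of short independent
trajectories of a ubiquitin-like fold (five β-strands I–V, one α-helix), the
package answers, quantitatively:

* **Which contacts break, in what order?**  Each frame is encoded by the
  4-bit state `*BCDE` of the β-sheet couplings B = (I,II), C = (I,V),
  D = (III,V), E = (III,IV) — a bit is 1 when the strands' centre-of-mass
  distance exceeds 0.7 nm — and probe-to-probe transitions build a
  16-state Markovian transition map with sources, sinks and dominant
  unfolding pathways (e.g. `CDEB`).
* **How reproducible is the unfolding?**  Ensemble RMSD and radius-of-
  gyration curves with the one-sigma-deviation-of-the-average σ/√N, and
  time-windowed Cα distance maps that locate the residue regions separating
  furthest (candidate FRET chromophore sites).
* **What would an X-ray detector see?**  Noise-free diffraction patterns
  I(q) = I₀ r_e² P dΩ |Σᵢ fᵢ(q) e^{2πi q·Rᵢ}|² on a virtual AGIPD-like
  detector (1024² × 200 μm pixels, 25 cm, 8 keV, 10¹² photons/100 nm
  focus), Fourier-Ring-Correlation resolution limits between half-ensemble
  averages (cutoff FRC = 0.5, resolution 1/q_max), and azimuthal
  ring-anisotropy profiles I_R(θ, t) that quantify SAXS detectability of
  the elongating molecule.

A first-class **synthetic trajectory generator** scripts the unfolding
(break order, break times, timing jitter, extension, thermal noise) so that
every analysis stage is testable against exact ground truth; it stands in
for the 100-run molecular-dynamics ensembles such studies are built on.
See `docs/methods.md` for the model, parameters and limitations.

## Worked example

```python
import fieldunfold as fu
from fieldunfold.scattering import RingPartition, frc_timeseries

top = fu.default_topology()                    # ubiquitin-like, 76 residues
mix = fu.field_strength_presets()["5e4"]       # moderate-field conditions
ens = fu.generate_ensemble(top, mix, n_runs=20, seed=1, n_frames=101, dt=0.5)

series = fu.ensemble_state_series(ens, top, dt_probe=0.5)
path = fu.dominant_pathway(series)
print(f"dominant pathway: {path.pathway} (frequency {path.frequency:.2f})")
print("sinks:", dict(fu.build_transition_map(series).sinks))

rmsd = fu.rmsd_ensemble(ens)
print(f"RMSD at 50 ps: {rmsd.mean[-1]:.2f} +/- {rmsd.sem[-1]:.3f} nm")

det = fu.DetectorConfig().binned(8)            # 128x128 px, same coverage
part = RingPartition.from_qmap(fu.build_q_map(det), n_rings=64)
print(frc_timeseries(fu.pattern_series(ens, det), part).head(4))
```

prints

```
dominant pathway: CDEB (frequency 0.95)
sinks: {'*1111': 20}
RMSD at 50 ps: 8.89 +/- 0.044 nm
   time_ps  resolution_angstrom status
0      0.0             4.382169     ok
1      5.0             4.535930     ok
2     10.0             5.620608     ok
3     15.0             5.501021     ok
```

Read: under moderate-field conditions the couplings break in the order
C → D → E → B in 19 of 20 runs, every run terminates fully unfolded
(`*1111`), the unfolded ensemble is tightly reproducible (σ/√N ≈ 0.04 nm on
an 8.9 nm RMSD), and the achievable SPI resolution transiently worsens from
~4.4 Å to ~5.6 Å exactly during the 10–15 ps window when run-to-run
structural heterogeneity peaks, recovering afterwards.

A CLI mirrors the pipeline stages for shell use:

```bash
fieldunfold generate --out runs/ --runs 100 --seed 1 --field 5e4
fieldunfold transitions --ensemble runs/ --dt-probe 0.05 --threshold 0.7
fieldunfold metrics --ensemble runs/
fieldunfold distmap --ensemble runs/ --window 0:10 --window 20:50
fieldunfold diffract --ensemble runs/ --bin 8 --out patterns.h5
fieldunfold frc --patterns patterns.h5 --cutoff 0.5
fieldunfold rings --patterns patterns.h5 --resolutions 5,10,15
```

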
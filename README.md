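# mpakit

Ensemble multiphoton-absorption analysis for snapshot-based spectroscopy of
protein-bound chromophores (e.g. the retinal Schiff base of
channelrhodopsin-2), plus toy-scale models of the electrostatic embedding
used to produce such data.

Snapshot-based spectroscopy computes excited states on hundreds of
molecular-dynamics frames and averages the broadened per-snapshot spectra.
`mpakit` is the post-processing layer of that workflow:

* **spectra** — one-, two- and three-photon absorption spectra from
  per-snapshot excited-state tables. Each state *i* with excitation energy
  ω<sub>i</sub> is broadened with a unit-area Lorentzian
  *g*(ω, ω<sub>i</sub>, γ<sub>i</sub>) of HWHM γ<sub>i</sub>:

  - OPA: ε(ω) = e²πN<sub>A</sub>/(2 ln10 ε₀ n m<sub>e</sub>c) ·
    Σ<sub>i</sub> (ω/ω<sub>i</sub>) f<sub>i</sub> g(ω, ω<sub>i</sub>, γ<sub>i</sub>)
    in L mol⁻¹ cm⁻¹,
  - TPA: σ(ω) = 2.505472×10⁻² Σ<sub>i</sub> ω² δ<sub>i</sub><sup>TPA</sup>
    g(2ω, ω<sub>i</sub>, γ<sub>i</sub>) in Göppert-Mayer units (a.u. inside the sum),
  - 3PA: σ(ω) = 7.781292×10⁻⁷ Σ<sub>i</sub> ω³ δ<sub>i</sub><sup>3PA</sup>
    g(3ω, ω<sub>i</sub>, γ<sub>i</sub>) in 10⁻⁸⁰ cm⁶ s²/photon²,

  with ensemble spectra as arithmetic means over snapshots, band-maximum
  tables and peak-deviation comparisons.
* **sampling** — snapshot decorrelation: the biased-normalization
  autocorrelation C(k) = 1/(nσ²) Σ<sub>t</sub>(x<sub>t</sub>−μ)(x<sub>t+k</sub>−μ),
  an A·exp(−t/τ) fit, a recommended sampling interval, and a down-sampling
  convergence study of the ensemble spectra.
* **structure** — chromophore descriptors on multi-frame XYZ/PDB
  trajectories: bond-length alternation BLA = (Σσ<sub>i</sub> − Σπ<sub>i</sub>)/5
  over five single/five double bonds, the ten backbone dihedrals, and the
  planarity P = Σ<sub>i</sub>(| |θ<sub>i</sub>| − 90 |)/90 ∈ [0, 10].
* **correlate** — nearest-time joins of descriptors with excitation
  energies and descriptive correlation statistics (Pearson, Spearman, OLS).
* **coupling** — a rigid point-charge cloud vs environment charges:
  exact Coulomb, single-center traceless Cartesian multipoles (orders 0–8),
  ESP-fitted charges, hybrid cutoff evaluation and (R_exact, p) error scans.
* **polarization** — self-consistent induced dipoles on polarizable sites
  with static charge/dipole/quadrupole fields and intra-fragment exclusion.
* **synthetic** — generators with machine-readable ground truth for all of
  the above (AR(1) excited-state ensembles, internal-coordinate polyene
  chains, structure-coupled energies, charge clouds, water-like fragments).

## Worked example

Decide a snapshot spacing from the autocorrelation of the two-photon cross
section (`examples/decorrelation.py`):

```text
fitted C(t) = 0.98 exp(-t/16.3 fs)
recommended snapshot spacing: 75 fs (residual correlation < 0.01)
```

The generator produced a series with a 15 fs correlation time; the fit
recovers it (16.3 fs) and converts it into the smallest frame multiple at
which residual correlation drops below 1%.

Correlate geometry with the first excitation energy
(`examples/structure_correlation.py`):

```text
BLA: mean 0.0994 Å, sd 0.0061 Å
planarity: mean 9.113 (10 = fully planar)
bla vs E1: r = +0.464, slope = +4.4517, n = 200
planarity vs E1: r = -0.079, slope = -0.0233, n = 200
generating BLA coefficient was +4.00 eV/Å
```

The positive BLA slope (within 15% of the generating +4.00 eV/Å) and the
negative planarity correlation reproduce the expected physics: a more
conjugated (low-BLA, planar) backbone has a lower first excitation energy.

The other examples cover ensemble spectrum assembly with peak tables
(`ensemble_spectra.py`), the hybrid-electrostatics error scan
(`coupling_scan.py`) and the induced-dipole solver (`induced_dipoles.py`).
A thin CLI mirrors the library (`mpakit --help`): `generate-ensemble`,
`generate-chain`, `spectra`, `acf`, `downsample`, `structure`, `correlate`,
`coupling-scan`, `polarize`.

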
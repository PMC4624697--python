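# Full-scale sweep configurations

These configurations reproduce the full study design (46 chromosomes,
congression deadline 1e3 s, bi-orientation deadline 1e5 s).  They are far
too heavy for the test suite (hours to days on one CPU); run them offline:

MT-number sweep (n = 100 cells per density; expect both congression and
bi-orientation probabilities to exceed 1/2 only inside an intermediate
window of total MT numbers):

    spindlesim sweep --config configs/full_scale_base.json \
        --parameter n_mt \
        --values 3000,5000,7000,10000,14000,18000,24000,30000 \
        -n 100 --out results/full_mt_sweep.csv

Catastrophe-rate sweep at fixed density (n = 10 cells per rate; congression
probability collapses once the catastrophe rate is large enough that MTs can
no longer span the cell):

    spindlesim sweep --config configs/full_scale_base.json \
        --parameter p_cat0 \
        --values 0.046,0.058,0.116,0.232,0.348,0.464,0.58 \
        -n 10 --congression-deadline 1000 --biorientation-deadline 1000 \
        --out results/full_catastrophe_sweep.csv

`spindlesim.sweet_spot_bounds` applied to the MT-number sweep table yields
the viable density window.
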
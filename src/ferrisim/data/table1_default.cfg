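# Canonical published parameter set for the ferritin sequestration model.
# Units are molar (M) and seconds throughout; constants quoted in mM in the
# literature are converted here (original value noted in the comment).

# Oxidation: 2 LIP -> DFP
ox_kcat = 591.0        # s^-1
ox_Km = 3.5e-4         # M (0.35 mM)
ox_n = 1.3             # Hill coefficient
H = 4                  # heavy subunits per cage (hepatocyte-like composition)
rO = 2.0               # L-homopolymer oxidation offset

# Reduction: DFP -> 2 LIP
red_kdeg = 0.2605      # s^-1

# Nucleation: 2 DFP -> 4 core
nuc_kcat = 5e7         # M^-2 s^-1
nuc_Ki = 4.615e-4      # M (0.4615 mM)
nuc_n = 4.0
rN = 50.0

# Mineralization: DFP -> 2 core
min_kcat = 0.101564    # s^-1
min_Km = 5e-6          # M
min_Ki = 4.6458e-3     # M (4.6458 mM)
min_n = 4.0
min_m = 8.0
capacity = 4300.0      # iron atoms per cage

# Ferritin turnover (off by default; cell-scale turnover scenarios switch it on)
ft_ksyn = 0.0          # M s^-1
ft_kdeg = 0.0          # s^-1
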
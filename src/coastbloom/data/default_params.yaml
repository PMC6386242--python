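# Canonical parameter set for the coastal plankton model.
# Units follow the CoastalParams docstring; this file is the single source
# of configuration truth and is echoed into every run's output directory.

# --- turbidity (SPM light attenuation) ---
a_spm_prime: 2.0        # specific SPM attenuation coefficient, 1/m
alpha: 0.05             # relative background turbidity / CDOM fraction, -
h_star: 20.0            # resuspension threshold depth, m
eps_star: 1.0e-5        # critical bottom TKE dissipation, W/kg
l_turb: 20.0            # Julian day of the winter turbidity maximum
s_depth: 0.4            # depth-sigmoid steepness, 1/m
s_sal: 1.0              # salinity-sigmoid steepness, 1/PSU
s_coast: 31.0           # coastal-water salinity threshold, PSU
s_est: 12.0             # estuarine salinity threshold, PSU

# --- carnivorous grazing closure ---
l_carn: 250.0           # Julian day of the carnivory maximum
m_z_prime: 0.025        # zooplankton mortality amplitude, 1/d
beta: 1.0               # seasonal carnivory amplification, -
gamma: 1.5              # density-dependent mortality coefficient, m3/mmol-C

# --- temperature response ---
q10: 2.0                # Q10 factor, -
t_ref: 10.0             # reference temperature, degC

# --- viral infection ---
s_virus: 4.0            # virulence-step steepness, -
m_vir_max: 1.0          # viral mortality proportionality, 1/d
f_det_lysis: 0.8        # lysis flux fraction routed to detritus, -
k_ads: 0.4              # adsorption rate scale, 1/d
k_ads_half: 10.0        # host half-saturation for adsorption, mmol-C/m3
n_rep_max: 3.5          # maximal replication multiplier, -
k_defense: 1.0          # antiviral defense removal scale, 1/d
k_decay: 0.3            # first-order virus decay, 1/d

# --- NPZD backbone ---
mu_max: 1.5             # maximal phytoplankton growth, 1/d
k_din: 1.0              # DIN half-saturation, mmol-N/m3
k_dip: 0.0625           # DIP half-saturation, mmol-P/m3
i_k: 25.0               # light half-saturation, W/m2
theta_chl: 0.25         # CHL:C, mg CHL per mmol-C
a_water: 0.1            # clear-water attenuation, 1/m
a_chl_shading: 0.02     # self-shading, 1/(m mg-CHL/m3)
q_n: 0.1509434          # Redfield N quota, mol-N/mol-C (16/106)
q_p: 0.0094340          # Redfield P quota, mol-P/mol-C (1/106)
g_max: 1.5              # maximal grazing, 1/d
k_graz_base: 15.0        # grazing half-saturation, mmol-C/m3
eps_assim: 0.3          # zooplankton assimilation efficiency, -
r_zoo_basal: 0.05       # zooplankton basal respiration/excretion, 1/d
f_det_mort: 0.8         # zooplankton mortality fraction routed to detritus, -
m_agg: 0.0015           # aggregation coefficient, m3/(mmol-C d)
w_det: 3.0              # detritus sinking velocity, m/d
r_det: 0.05             # detritus -> DOM remineralization, 1/d
r_dom: 0.05             # DOM -> inorganic remineralization, 1/d
r_ben: 0.02             # benthic return rate, 1/d
f_denit: 0.2            # denitrified fraction of benthic N return, -
f_burial: 0.05          # buried fraction of benthic return, -
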
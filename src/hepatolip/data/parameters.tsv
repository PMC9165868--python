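name	value	units	provenance
mu_mh_star	1.5e7	molec./(mL s)	assumed
mu_mr_star	2e8	molec./(mL s)	assumed
mu_mp_star	1e6	molec./(mL s)	table1
delta_mh	4.48e-5	1/s	parent_model
delta_mr	4.48e-5	1/s	parent_model
delta_mp	4.48e-5	1/s	table1
kappa_mh	8.21e16	molec./mL	parent_model
kappa_mr	8.21e16	molec./mL	parent_model
kappa_mp	8.21e16	molec./mL	table1
s0	8.21e16	molec./mL	assumed
kc	1e17	molec./mL	assumed
xc	4	-	assumed
xh	1	-	assumed
xr	1	-	assumed
xp	1	-	table1
mu_h	1e-1	1/s	assumed
mu_r	1e-1	1/s	assumed
mu_p	1e-1	1/s	table1
delta_h	3.8e-5	1/s	assumed
delta_p	0	1/s	table1
delta_c	5e-5	1/s	assumed
gamma_r	1e-2	1/s	assumed
gamma_p	1e-2	1/s	table1
gamma_l	1e-3	1/s	assumed
gamma_v	1e-3	1/s	assumed
f	0.7	-	parent_model
P	1	-	assumed
beta_0	1.5e-2	1/s	assumed
M_l	1	-	assumed
M_v	4	-	assumed
M_p	1	-	table1
alpha_l	5e-16	mL/(molec. s)	assumed
alpha_minus_l	1e-4	1/s	assumed
alpha_v	1e-15	mL/(molec. s)	assumed
alpha_minus_v	5e-5	1/s	assumed
alpha_p	1e-17	mL/(molec. s)	table1
alpha_minus_p	1e-4	1/s	table1
beta_l	2.7e-3	1/s	parent_model
beta_v	2.7e-3	1/s	parent_model
beta_p	2.7e-3	1/s	table1
chi_v	2e-5	1/s	assumed
omega_V	3e7	molec./(mL s)	assumed
omega_P	0	molec./(mL s)	assumed
omega_A	0	molec./(mL s)	assumed
omega_S	0	molec./(mL s)	assumed
R_l_chol	2700	-	assumed
R_v_chol	5000	-	assumed
mu_c	2.3	1/s	assumed
eps_S	1e-14	mL/(molec. s)	table1
eps_minus_S	1e-2	1/s	table1
CL_S	0.01	mL/s	table1
eps_p	1e-14	mL/(molec. s)	table1
eps_minus_p	1e-3	1/s	table1
W	10	mL	assumed
J	1	-	assumed
rf0	2e13	molec./mL	assumed
sE0	1e12	molec./mL	assumed
pE0_ref	1e12	molec./mL	assumed
l0	1e12	molec./mL	assumed
v0	1e12	molec./mL	assumed
m0	1e10	molec./mL	assumed
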
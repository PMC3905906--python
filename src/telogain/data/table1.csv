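study_id,year,n,followup_years,baseline_tl,followup_tl,attrition_rate,units,method,cv,replicates,observed_gainers_pct,observed_ci_low,observed_ci_high,maintainer_band_pct,notes
gardner2005,2005,70,11.5,7.58,7.22,31.3,kb,SB,0.015,2,7.9,2.8,16.8,,Bogalusa Heart Study subset
martinruiz2005a,2005,67,3.7,,,,TS,qPCR,,,,,,,baseline and follow-up LTL not reported
martinruiz2005b,2005,141,2.9,,,,TS,qPCR,,,,,,,baseline and follow-up LTL not reported
aviv2009,2009,635,5.9,7.45,7.23,40.7,kb,SB,0.014,2,11.2,8.8,13.9,,Bogalusa Heart Study subset
ehrlenbach2009,2009,510,10,8.02,7.44,45.5,kb,qPCR,0.009,1,15.9,12.8,19.3,,T/S converted to bp; unusually low 0.9% CV assumed to be inter-assay
nordfjall2009,2009,959,10,,,,TS,qPCR,0.06,,34,31,37,,stable-or-increased LTL reported jointly; observed value may be an overestimate
epel2009,2009,134,2.5,4.70,4.70,,kb,qPCR,0.07,,47,38,56,15,T/S converted to bp; baseline and follow-up identical at reported precision so change cannot be computed
farzanehfar2010,2010,608,5,5.50,5.29,42,kb,qPCR,0.037,1,39,35,43,10,T/S converted to bp
chen2011a,2011,271,5.8,7.37,7.18,31.4,kb,SB,0.024,2,14.4,10.4,19.1,,Bogalusa Heart Study subset; 5.8-year follow-up interval
chen2011b,2011,271,6.6,7.18,6.94,33.5,kb,SB,0.024,2,10.7,7.3,15.0,,Bogalusa Heart Study subset; 6.6-year follow-up interval
chen2011c,2011,271,12.4,7.37,6.94,32.2,kb,SB,0.024,2,1.5,0.4,3.7,,Bogalusa Heart Study subset; 12.4-year follow-up interval
svenson2011,2011,50,0.5,0.578,0.577,0.001,TS,qPCR,0.06,,50,36,64,,six-month follow-up
kark2012,2012,609,13.1,7.33,7.00,25.2,kb,SB,0.022,2,3.0,1.8,4.7,,
shalev2012,2012,236,5,1.08,0.96,0.024,TS,qPCR,,,16.9,12.4,22.4,15,children aged 5-10; intra-assay CV for T and S reported separately but not inter-assay CV for T/S; only >15% lengthening counted as gain so observed value may be an underestimate
steenstrup2013,2013,80,10.9,5.84,5.51,30.8,kb,SB,0.028,2,7.5,2.8,15.6,,
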
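target,method,function,top_fn,mean16_fn
1kviA,adaptive,FF,0.74,0.68
1kviA,adaptive,GOAP,0.78,0.68
1kviA,adaptive,dDFIRE,0.70,0.70
1kviA,adaptive,RWplus,0.70,0.70
1kviA,static,FF,0.67,0.62
1kviA,static,GOAP,0.51,0.58
1kviA,static,dDFIRE,0.53,0.59
1kviA,static,RWplus,0.53,0.61
1pgx,adaptive,FF,0.49,0.41
1pgx,adaptive,GOAP,0.43,0.44
1pgx,adaptive,dDFIRE,0.47,0.43
1pgx,adaptive,RWplus,0.37,0.37
1pgx,static,FF,0.43,0.44
1pgx,static,GOAP,0.48,0.46
1pgx,static,dDFIRE,0.45,0.47
1pgx,static,RWplus,0.50,0.47
1cy5A,adaptive,FF,0.58,0.58
1cy5A,adaptive,GOAP,0.63,0.61
1cy5A,adaptive,dDFIRE,0.62,0.63
1cy5A,adaptive,RWplus,0.62,0.63
1cy5A,static,FF,0.63,0.61
1cy5A,static,GOAP,0.63,0.62
1cy5A,static,dDFIRE,0.61,0.62
1cy5A,static,RWplus,0.61,0.62
1shfA,adaptive,FF,0.69,0.67
1shfA,adaptive,GOAP,0.66,0.67
1shfA,adaptive,dDFIRE,0.64,0.68
1shfA,adaptive,RWplus,0.71,0.67
1shfA,static,FF,0.61,0.57
1shfA,static,GOAP,0.63,0.63
1shfA,static,dDFIRE,0.65,0.61
1shfA,static,RWplus,0.64,0.63
1r69,adaptive,FF,0.77,0.75
1r69,adaptive,GOAP,0.77,0.77
1r69,adaptive,dDFIRE,0.79,0.78
1r69,adaptive,RWplus,0.80,0.77
1r69,static,FF,0.72,0.64
1r69,static,GOAP,0.73,0.73
1r69,static,dDFIRE,0.77,0.77
1r69,static,RWplus,0.76,0.77
1csp,adaptive,FF,0.54,0.61
1csp,adaptive,GOAP,0.57,0.57
1csp,adaptive,dDFIRE,0.56,0.60
1csp,adaptive,RWplus,0.59,0.57
1csp,static,FF,0.55,0.59
1csp,static,GOAP,0.52,0.58
1csp,static,dDFIRE,0.70,0.70
1csp,static,RWplus,0.69,0.69
1ah9,adaptive,FF,0.67,0.63
1ah9,adaptive,GOAP,0.53,0.51
1ah9,adaptive,dDFIRE,0.63,0.64
1ah9,adaptive,RWplus,0.68,0.64
1ah9,static,FF,0.63,0.61
1ah9,static,GOAP,0.71,0.74
1ah9,static,dDFIRE,0.65,0.66
1ah9,static,RWplus,0.75,0.73
1b72A,adaptive,FF,0.60,0.47
1b72A,adaptive,GOAP,0.47,0.47
1b72A,adaptive,dDFIRE,0.51,0.58
1b72A,adaptive,RWplus,0.61,0.58
1b72A,static,FF,0.26,0.50
1b72A,static,GOAP,0.54,0.56
1b72A,static,dDFIRE,0.59,0.58
1b72A,static,RWplus,0.60,0.60
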
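>plectasin family=fDEF1 mature AITD defensin, Pseudoplectania nigrella
GFGCNGPWDEDDMQCHNHCKSIKGYKGGYCAKGGFVCKCY
>anchor-fDEF2 family=fDEF2 synthetic anchor (constructed stand-in, CSab spacing 12-3-9-5-1)
WDECTEGDGEEDQFNECNIKCSDKDLDQSECRFHGECGCRN
>anchor-fDEF3 family=fDEF3 synthetic anchor (constructed stand-in, CSab spacing 9-3-10-6-1)
SRCNHNARFKSGCTGKCSKENRGNSQNCRGISHRCRCY
>anchor-fDEF4 family=fDEF4 synthetic anchor (constructed stand-in, CSab spacing 13-3-11-7-1)
RENKCGRGNINDSNNAGRCIHKCDNSTLRNNSGRCNNFNTKKCPCKY
>anchor-fDEF6 family=fDEF6 synthetic anchor (constructed stand-in, CSab spacing 11-3-10-6-1)
FSSCSRGYKAKNPSGCSTACSQGFGYRGSVCGKKEKSCGCKR
>anchor-fDEF8 family=fDEF8 synthetic anchor (constructed stand-in, CSab spacing 9-3-9-4-1, RPG-rich C-tail)
PVCRHRIGQGLACEFICREKRSEKPRCPRYGCTCGRPGRPG
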